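"""ABC random-forest inference: scenario choice and parameter estimation.

A reference table of simulated records (scenario label, parameter draw,
summary-statistic vector) trains the forests. Scenario choice uses a
classification forest on the statistics plus linear-discriminant (LDA)
axes; the chosen scenario's rows then train one regression forest per
parameter on the statistics plus partial-least-squares (PLS) components.
Out-of-bag (OOB) records provide the global prior error rate, per-scenario
class errors, normalized mean absolute errors and interval coverage;
posterior (local) quantities are computed at the observed dataset's
position in feature space following the regression-on-OOB-errors
construction of ABC-RF.
"""
from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from sklearn.cross_decomposition import PLSRegression
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .coalescent import simulate_dataset
from .scenarios import ScenarioSet, sample_draw
from .sumstats import feature_names, summarize_dataset

__all__ = [
    "ReferenceTable",
    "ScenarioChoiceResult",
    "ParameterEstimate",
    "build_reference_table",
    "append_lda_axes",
    "scenario_choice",
    "estimate_parameters",
    "replicate_analysis",
]

# Forest defaults follow the random-forest ABC convention: mtry = sqrt(p)
# and unlimited depth. Trees use 5-observation leaves (the ranger
# regression default, standard for quantile forests) and are grown on a
# bootstrap subsample of DEFAULT_MAX_SAMPLES of the table; both are
# tractability choices that leave OOB error estimates essentially
# unchanged (see the methods note) while keeping training time and forest
# memory linear in the subsample size.
DEFAULT_MAX_SAMPLES = 0.25
DEFAULT_MIN_LEAF = 5


@dataclass
class ReferenceTable:
    """Simulated training records for the forests.

    ``stats`` holds one row of summary statistics per simulated dataset,
    ``scenario`` the generating scenario id, ``params`` the parameter draw
    (NaN for parameters a scenario does not use). LDA axis scores and the
    fitted projection are attached by :func:`append_lda_axes`.
    """

    stats: np.ndarray
    scenario: np.ndarray
    params: pd.DataFrame
    feature_names: list[str]
    provenance: dict = field(default_factory=dict)
    lda_scores: np.ndarray | None = None
    _lda: LinearDiscriminantAnalysis | None = None
    _lda_cols: np.ndarray | None = None

    @property
    def n_rows(self) -> int:
        return self.stats.shape[0]

    def features(self, with_lda: bool = True) -> np.ndarray:
        if with_lda and self.lda_scores is not None:
            return np.hstack([self.stats, self.lda_scores]).astype(np.float32)
        return self.stats.astype(np.float32)

    def project_observed(self, observed: np.ndarray) -> np.ndarray:
        """LDA axis scores for an observed statistic vector."""
        if self._lda is None:
            raise ValueError("append_lda_axes has not been run on this table")
        obs = np.atleast_2d(observed)[:, self._lda_cols]
        return self._lda.transform(obs)

    def observed_features(self, observed: np.ndarray) -> np.ndarray:
        obs = np.atleast_2d(observed)
        if self.lda_scores is not None:
            return np.hstack([obs, self.project_observed(observed)]).astype(np.float32)
        return obs.astype(np.float32)

    def restrict(self, scenario_id: int) -> "ReferenceTable":
        m = self.scenario == scenario_id
        return ReferenceTable(
            stats=self.stats[m],
            scenario=self.scenario[m],
            params=self.params.loc[m].reset_index(drop=True),
            feature_names=list(self.feature_names),
            provenance=dict(self.provenance, restricted_to=scenario_id),
        )

    def table_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.stats).tobytes())
        h.update(np.ascontiguousarray(self.scenario).tobytes())
        h.update(self.params.to_csv(index=False).encode())
        return h.hexdigest()

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.stats, columns=self.feature_names)
        df.insert(0, "scenario", self.scenario)
        for c in self.params.columns:
            df[f"param_{c}"] = self.params[c].to_numpy()
        if self.lda_scores is not None:
            for k in range(self.lda_scores.shape[1]):
                df[f"LDA{k + 1}"] = self.lda_scores[:, k]
        return df


def save_reference_table(table: ReferenceTable, path: str) -> None:
    """Write a reference table as delimited text with a provenance header."""
    prov = {k: v for k, v in table.provenance.items() if k != "shuffle"}
    with open(path, "w") as fh:
        fh.write(f"# msatabc reference table\n# provenance: {prov}\n")
        fh.write(f"# hash: {table.table_hash()}\n")
        table.to_frame().to_csv(fh, sep="\t", index=False)


def load_reference_table(path: str) -> ReferenceTable:
    """Read a reference table written by :func:`save_reference_table`.

    LDA scores are not persisted as fitted projections; rerun
    :func:`append_lda_axes` after loading if axis columns are needed.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    param_cols = [c for c in df.columns if c.startswith("param_")]
    lda_cols = [c for c in df.columns if c.startswith("LDA")]
    feat_cols = [
        c for c in df.columns if c not in param_cols + lda_cols + ["scenario"]
    ]
    return ReferenceTable(
        stats=df[feat_cols].to_numpy(dtype=np.float64),
        scenario=df["scenario"].to_numpy(dtype=np.int64),
        params=df[param_cols].rename(columns=lambda c: c[len("param_"):]),
        feature_names=feat_cols,
        provenance={"loaded_from": path},
    )


@dataclass
class ScenarioChoiceResult:
    """Votes, posterior probability and error rates for a scenario choice."""

    scenario_ids: np.ndarray
    votes: np.ndarray
    selected: int
    tie: bool
    posterior_probability: float | None
    prior_error: float
    class_errors: dict[int, float]
    local_error: float | None
    lda_projection: np.ndarray | None
    n_trees: int


@dataclass
class ParameterEstimate:
    """Point estimates, 90 % interval and accuracy metrics for one parameter."""

    parameter: str
    mean: float
    median: float
    q05: float
    q95: float
    global_nmae: float
    local_nmae: float | None
    coverage90: float

    def __post_init__(self) -> None:
        if not (self.q05 <= self.median <= self.q95):
            raise ValueError(
                f"{self.parameter}: quantile ordering violated "
                f"({self.q05}, {self.median}, {self.q95})"
            )


# --------------------------------------------------------------------------
# reference table


def build_reference_table(
    scenario_set: ScenarioSet,
    n_per_scenario: int,
    seed: int,
    scenario_ids: list[int] | None = None,
    missing_rate: float = 0.0,
) -> ReferenceTable:
    """Simulate the ABC training table: draws → datasets → statistics.

    The design is balanced (``n_per_scenario`` rows per scenario); rows are
    shuffled with the permutation recorded in provenance. Deterministic for
    a given seed.
    """
    if n_per_scenario < 1:
        raise ValueError("n_per_scenario must be >= 1")
    scenarios = (
        scenario_set.scenarios
        if scenario_ids is None
        else [scenario_set.get(i) for i in scenario_ids]
    )
    rng = np.random.default_rng(seed)
    pops = [lin.id for lin in scenarios[0].lineages]
    fnames = feature_names(pops)
    all_params = sorted({p for sc in scenarios for p in sc.param_names()} | {"mu_mean", "p_mean"})
    n_total = n_per_scenario * len(scenarios)
    stats = np.empty((n_total, len(fnames)), dtype=np.float64)
    labels = np.empty(n_total, dtype=np.int64)
    pmat = np.full((n_total, len(all_params)), np.nan)
    row = 0
    for sc in scenarios:
        for _ in range(n_per_scenario):
            draw = sample_draw(scenario_set.priors, sc, rng, n_loci=len(scenario_set.loci))
            ds = simulate_dataset(sc, draw, scenario_set.loci, rng, missing_rate=missing_rate)
            stats[row] = summarize_dataset(ds)
            labels[row] = sc.id
            for j, p in enumerate(all_params):
                if p in draw.values:
                    pmat[row, j] = draw.values[p]
            row += 1
    perm = rng.permutation(n_total)
    table = ReferenceTable(
        stats=stats[perm],
        scenario=labels[perm],
        params=pd.DataFrame(pmat[perm], columns=all_params),
        feature_names=fnames,
        provenance={
            "seed": seed,
            "n_per_scenario": n_per_scenario,
            "scenario_ids": [sc.id for sc in scenarios],
            "missing_rate": missing_rate,
            "shuffle": perm,
        },
    )
    return table


def append_lda_axes(table: ReferenceTable) -> ReferenceTable:
    """Fit linear discriminant axes on (statistics → scenario) and append
    the axis scores as extra feature columns.

    For k scenarios min(k − 1, rank) axes are produced; constant columns
    are dropped (with a warning) before the fit, and the projection is
    stored so observed vectors are transformed identically.
    """
    if len(np.unique(table.scenario)) < 2:
        raise ValueError("LDA axes require at least two scenarios")
    keep = table.stats.std(axis=0) > 0
    if not keep.all():
        dropped = [n for n, k in zip(table.feature_names, keep) if not k]
        warnings.warn(f"dropping constant feature columns for LDA: {dropped}")
    lda = LinearDiscriminantAnalysis(solver="svd")
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*collinear.*")
        scores = lda.fit_transform(table.stats[:, keep], table.scenario)
    table.lda_scores = scores
    table._lda = lda
    table._lda_cols = keep
    return table


# --------------------------------------------------------------------------
# scenario choice


def fit_scenario_forest(
    table: ReferenceTable,
    n_trees: int = 2000,
    seed: int | None = 0,
    max_samples: float | None = DEFAULT_MAX_SAMPLES,
    min_samples_leaf: int = DEFAULT_MIN_LEAF,
) -> RandomForestClassifier:
    """Train the scenario-choice classification forest on a table with LDA
    axes; reusable across :func:`scenario_choice` calls and test-set
    prediction."""
    if table.lda_scores is None:
        raise ValueError("run append_lda_axes on the table first")
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        bootstrap=True,
        oob_score=True,
        max_samples=max_samples,
        min_samples_leaf=min_samples_leaf,
        n_jobs=1,
        random_state=None if seed is None else int(seed),
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*Some inputs do not have OOB.*")
        rf.fit(table.features(with_lda=True), table.scenario)
    return rf


def predict_scenarios(
    table: ReferenceTable, forest: RandomForestClassifier, stats: np.ndarray
) -> np.ndarray:
    """Predicted scenario ids for a matrix of summary-statistic vectors."""
    stats = np.atleast_2d(stats)
    X = np.hstack([stats, table.project_observed(stats)]).astype(np.float32)
    return forest.predict(X)


def scenario_choice(
    table: ReferenceTable,
    observed: np.ndarray,
    n_trees: int = 2000,
    seed: int | None = 0,
    max_samples: float | None = DEFAULT_MAX_SAMPLES,
    min_samples_leaf: int = DEFAULT_MIN_LEAF,
    compute_posterior: bool = True,
    error_forest_trees: int | None = None,
    forest: RandomForestClassifier | None = None,
) -> ScenarioChoiceResult:
    """Choose among scenarios with a classification forest.

    Votes are the per-tree predictions at ``observed``; the prior error
    rate is the OOB misclassification frequency, the class errors its
    per-scenario decomposition. The posterior probability of the selected
    scenario is 1 − E[error | observed], estimated by a regression forest
    fit to the OOB misclassification indicators; the local error is its
    complement.
    """
    if table.lda_scores is None:
        raise ValueError("run append_lda_axes on the table before scenario_choice")
    observed = np.asarray(observed, dtype=np.float64)
    if observed.ndim != 1 or observed.size != table.stats.shape[1]:
        raise ValueError(
            f"observed vector has {observed.size} features, table has "
            f"{table.stats.shape[1]}"
        )
    if n_trees < 50:
        warnings.warn(f"n_trees = {n_trees} is small; votes will be unstable")
    X = table.features(with_lda=True)
    y = table.scenario
    if forest is None:
        forest = fit_scenario_forest(
            table,
            n_trees=n_trees,
            seed=seed,
            max_samples=max_samples,
            min_samples_leaf=min_samples_leaf,
        )
    rf = forest
    n_trees = rf.n_estimators

    obs_row = table.observed_features(observed)
    classes = rf.classes_
    # sub-estimators predict encoded class indices 0..k-1
    tree_preds = np.stack([est.predict(obs_row) for est in rf.estimators_]).ravel()
    votes = np.bincount(tree_preds.astype(np.int64), minlength=classes.size)
    top = votes.max()
    winners = classes[votes == top]
    tie = winners.size > 1
    if tie:
        warnings.warn(f"vote tie between scenarios {list(winners)}; lowest id selected")
    selected = int(winners.min())

    oob = rf.oob_decision_function_
    valid = ~np.isnan(oob).any(axis=1)
    oob_pred = classes[np.argmax(oob[valid], axis=1)]
    mis = (oob_pred != y[valid]).astype(np.float64)
    prior_error = float(mis.mean())
    class_errors = {
        int(c): float(mis[y[valid] == c].mean()) for c in classes
    }

    posterior = local_error = None
    if compute_posterior:
        n_err_trees = error_forest_trees or min(n_trees, 500)
        err_rf = RandomForestRegressor(
            n_estimators=n_err_trees,
            max_features="sqrt",
            min_samples_leaf=5,
            max_samples=max_samples,
            n_jobs=1,
            random_state=None if seed is None else int(seed) + 1,
        )
        err_rf.fit(X[valid], mis)
        local_error = float(err_rf.predict(obs_row)[0])
        posterior = 1.0 - local_error

    return ScenarioChoiceResult(
        scenario_ids=classes,
        votes=votes,
        selected=selected,
        tie=tie,
        posterior_probability=posterior,
        prior_error=prior_error,
        class_errors=class_errors,
        local_error=local_error,
        lda_projection=table.project_observed(observed)[0],
        n_trees=n_trees,
    )


# --------------------------------------------------------------------------
# parameter estimation (quantile regression forest machinery)


def _n_bootstrap(n: int, max_samples: float | None) -> int:
    if max_samples is None:
        return n
    return max(int(round(n * max_samples)), 1)


def _inbag_matrix(forest, n: int) -> np.ndarray:
    """Bootstrap multiplicity of each training row in each tree."""
    try:  # sklearn's own bootstrap index generator, if available
        from sklearn.ensemble._forest import (
            _generate_sample_indices,
            _get_n_samples_bootstrap,
        )

        n_boot = _get_n_samples_bootstrap(n, forest.max_samples)
        index_fn = lambda est: _generate_sample_indices(est.random_state, n, n_boot)
    except Exception:  # pragma: no cover - fallback mirrors sklearn's logic
        n_boot = _n_bootstrap(n, forest.max_samples)
        index_fn = lambda est: np.random.RandomState(est.random_state).randint(
            0, n, n_boot
        )
    inbag = np.zeros((n, forest.n_estimators), dtype=np.int32)
    for t, est in enumerate(forest.estimators_):
        np.add.at(inbag[:, t], index_fn(est), 1)
    return inbag


@njit(cache=True)
def _qrf_weights_core(order, sorted_leaves, inbag, leaves_q, allowed):  # pragma: no cover
    """Leaf co-membership weights of training rows for each query point.

    ``order``/``sorted_leaves`` give, per tree, training rows sorted by
    leaf id; ``inbag`` the bootstrap multiplicities; ``leaves_q`` the query
    leaf per tree; ``allowed`` masks the trees usable for each query (e.g.
    only trees where an OOB evaluation row was out of bag).
    """
    n, T = order.shape[0], order.shape[1]
    m = leaves_q.shape[0]
    W = np.zeros((m, n), np.float64)
    for q in range(m):
        used = 0
        for t in range(T):
            if not allowed[q, t]:
                continue
            leaf = leaves_q[q, t]
            lo = np.searchsorted(sorted_leaves[:, t], leaf, side="left")
            hi = np.searchsorted(sorted_leaves[:, t], leaf, side="right")
            tot = 0.0
            for k in range(lo, hi):
                tot += inbag[order[k, t], t]
            if tot <= 0.0:
                continue
            for k in range(lo, hi):
                j = order[k, t]
                if inbag[j, t] > 0:
                    W[q, j] += inbag[j, t] / tot
            used += 1
        if used > 0:
            for j in range(n):
                W[q, j] /= used
    return W


def _weighted_quantiles(y: np.ndarray, w: np.ndarray, qs: tuple[float, ...]) -> list[float]:
    """Weighted quantiles with midpoint positions and linear interpolation."""
    order = np.argsort(y)
    ys, ws = y[order], w[order]
    cum = np.cumsum(ws)
    tot = cum[-1]
    if tot <= 0:
        return [float(np.median(y))] * len(qs)
    pos = (cum - 0.5 * ws) / tot
    return [float(np.interp(q, pos, ys)) for q in qs]


def _qrf_machinery(forest, X_train: np.ndarray):
    n = X_train.shape[0]
    leaves_train = forest.apply(X_train).astype(np.int64)
    inbag = _inbag_matrix(forest, n)
    order = np.argsort(leaves_train, axis=0, kind="stable").astype(np.int64)
    sorted_leaves = np.take_along_axis(leaves_train, order, axis=0)
    return leaves_train, inbag, order, sorted_leaves


def estimate_parameters(
    table: ReferenceTable,
    observed: np.ndarray | None,
    parameters: list[str],
    n_trees: int = 2000,
    pls_axes: int = 5,
    n_oob: int = 1000,
    seed: int | None = 0,
    max_samples: float | None = 0.5,
    interval: tuple[float, float] = (0.05, 0.95),
) -> dict[str, ParameterEstimate]:
    """Regression-forest posterior summaries for the chosen scenario.

    The table must be restricted to a single scenario. Per parameter, a
    regression forest is grown on the summary statistics plus the first
    ``pls_axes`` PLS components (computed against that parameter). Point
    estimates at the observed vector are the forest mean and the
    weighted median of training responses under quantile-forest leaf
    weights; the 90 % interval comes from the same weights. Global NMAE
    is computed over ``n_oob`` out-of-bag evaluation rows, the local NMAE
    weights those rows by similarity to the observed dataset, and
    coverage is the fraction of evaluation rows whose true value falls in
    their own OOB-based 90 % interval.
    """
    if len(np.unique(table.scenario)) != 1:
        raise ValueError("restrict the table to the chosen scenario first")
    rng = np.random.default_rng(seed)
    results: dict[str, ParameterEstimate] = {}
    n = table.n_rows
    base = table.stats
    for param in parameters:
        if param not in table.params.columns or table.params[param].isna().all():
            raise ValueError(f"parameter {param!r} absent from the table's draws")
        y = table.params[param].to_numpy(dtype=np.float64)
        n_comp = min(pls_axes, base.shape[1], max(n - 1, 1))
        pls = PLSRegression(n_components=n_comp, scale=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pls.fit(base, y)
            Xp = np.hstack([base, pls.transform(base)]).astype(np.float32)
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            max_features="sqrt",
            min_samples_leaf=5,
            bootstrap=True,
            oob_score=True,
            max_samples=max_samples,
            n_jobs=1,
            random_state=int(rng.integers(2**31 - 1)),
        )
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*Some inputs do not have OOB.*")
            forest.fit(Xp, y)
        leaves_train, inbag, order, sorted_leaves = _qrf_machinery(forest, Xp)

        oob_pred = forest.oob_prediction_
        has_oob = ~np.isnan(oob_pred)
        eval_idx = np.flatnonzero(has_oob)
        if eval_idx.size > n_oob:
            eval_idx = rng.choice(eval_idx, size=n_oob, replace=False)
        rel_err = np.abs(oob_pred[eval_idx] - y[eval_idx]) / np.abs(y[eval_idx])
        global_nmae = float(rel_err.mean())

        # per-evaluation-row OOB intervals -> coverage
        allowed = inbag[eval_idx] == 0
        Wev = _qrf_weights_core(
            order, sorted_leaves, inbag, leaves_train[eval_idx], allowed
        )
        lo_q, hi_q = interval
        covered = 0
        for k in range(eval_idx.size):
            lo, hi = _weighted_quantiles(y, Wev[k], (lo_q, hi_q))
            if lo <= y[eval_idx[k]] <= hi:
                covered += 1
        coverage = covered / max(eval_idx.size, 1)

        if observed is not None:
            obs = np.asarray(observed, dtype=np.float64).reshape(1, -1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                obs_f = np.hstack([obs, pls.transform(obs)]).astype(np.float32)
            mean = float(forest.predict(obs_f)[0])
            leaves_obs = forest.apply(obs_f).astype(np.int64)
            Wobs = _qrf_weights_core(
                order,
                sorted_leaves,
                inbag,
                leaves_obs,
                np.ones((1, forest.n_estimators), dtype=np.bool_),
            )[0]
            med, q05, q95 = _weighted_quantiles(y, Wobs, (0.5, lo_q, hi_q))
            q05, med, q95 = sorted((q05, med, q95))
            wl = Wobs[eval_idx]
            local_nmae = (
                float((wl * rel_err).sum() / wl.sum()) if wl.sum() > 0 else None
            )
        else:
            mean = float(y.mean())
            med, q05, q95 = _weighted_quantiles(
                y, np.ones_like(y) / y.size, (0.5, lo_q, hi_q)
            )
            local_nmae = None

        results[param] = ParameterEstimate(
            parameter=param,
            mean=mean,
            median=med,
            q05=q05,
            q95=q95,
            global_nmae=global_nmae,
            local_nmae=local_nmae,
            coverage90=coverage,
        )
    return results


def predict_intervals(
    table: ReferenceTable,
    test_stats: np.ndarray,
    parameters: list[str],
    n_trees: int = 2000,
    pls_axes: int = 5,
    seed: int | None = 0,
    max_samples: float | None = 0.5,
    interval: tuple[float, float] = (0.05, 0.95),
) -> dict[str, dict[str, np.ndarray]]:
    """Forest point estimates and quantile intervals for many test vectors.

    Used for parameter-recovery studies: one forest per parameter is
    trained on the (single-scenario) table, then every row of
    ``test_stats`` gets a mean prediction and a weighted-quantile interval.
    """
    if len(np.unique(table.scenario)) != 1:
        raise ValueError("restrict the table to the chosen scenario first")
    rng = np.random.default_rng(seed)
    base = table.stats
    test_stats = np.atleast_2d(test_stats)
    out: dict[str, dict[str, np.ndarray]] = {}
    for param in parameters:
        y = table.params[param].to_numpy(dtype=np.float64)
        n_comp = min(pls_axes, base.shape[1], max(table.n_rows - 1, 1))
        pls = PLSRegression(n_components=n_comp, scale=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pls.fit(base, y)
            Xp = np.hstack([base, pls.transform(base)]).astype(np.float32)
            Xt = np.hstack([test_stats, pls.transform(test_stats)]).astype(np.float32)
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            max_features="sqrt",
            min_samples_leaf=5,
            bootstrap=True,
            max_samples=max_samples,
            n_jobs=1,
            random_state=int(rng.integers(2**31 - 1)),
        )
        forest.fit(Xp, y)
        leaves_train, inbag, order, sorted_leaves = _qrf_machinery(forest, Xp)
        leaves_t = forest.apply(Xt).astype(np.int64)
        W = _qrf_weights_core(
            order,
            sorted_leaves,
            inbag,
            leaves_t,
            np.ones((Xt.shape[0], forest.n_estimators), dtype=np.bool_),
        )
        lo_q, hi_q = interval
        means = forest.predict(Xt)
        med = np.empty(Xt.shape[0])
        lo = np.empty(Xt.shape[0])
        hi = np.empty(Xt.shape[0])
        for k in range(Xt.shape[0]):
            m_, l_, h_ = _weighted_quantiles(y, W[k], (0.5, lo_q, hi_q))
            l_, m_, h_ = sorted((l_, m_, h_))
            med[k], lo[k], hi[k] = m_, l_, h_
        out[param] = {"mean": means, "median": med, "q05": lo, "q95": hi}
    return out


def replicate_analysis(
    table: ReferenceTable,
    observed: np.ndarray,
    n_replicates: int,
    seed: int = 0,
    n_trees: int = 2000,
    **kwargs,
) -> pd.DataFrame:
    """Rerun the scenario-choice forest with fresh seeds on a fixed table.

    Mirrors the replicate-analysis protocol (same training data, new
    forests); returns per-output mean and SD across replicates, with votes
    reported per scenario.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_replicates):
        res = scenario_choice(
            table, observed, n_trees=n_trees, seed=int(rng.integers(2**31 - 1)), **kwargs
        )
        row = {f"votes_{s}": v for s, v in zip(res.scenario_ids, res.votes)}
        row["selected"] = res.selected
        row["prior_error"] = res.prior_error
        if res.posterior_probability is not None:
            row["posterior_probability"] = res.posterior_probability
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.agg(["mean", "std"]).T
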