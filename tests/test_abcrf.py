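import warnings

import numpy as np
import pandas as pd
import pytest

from msatabc import (
    LocusSpec,
    PriorSet,
    ReferenceTable,
    append_lda_axes,
    build_reference_table,
    estimate_parameters,
    load_reference_table,
    replicate_analysis,
    save_reference_table,
    scenario_choice,
)
from msatabc.scenarios import (
    DemographicEvent,
    DemographicScenario,
    Lineage,
    ScenarioSet,
)


def toy_scenario_set():
    """Two scenarios with the same two-population topology but disjoint Ne
    priors — trivially separable from the diversity statistics."""
    loci = [LocusSpec(f"L{i}", 20, 40) for i in range(5)]
    scenarios = []
    for sid, tag in ((1, "small"), (2, "big")):
        scenarios.append(
            DemographicScenario(
                id=sid,
                lineages=[
                    Lineage("A", f"NeA_{tag}", 30),
                    Lineage("B", f"NeB_{tag}", 30),
                ],
                events=[
                    DemographicEvent(
                        kind="split", time_param="t1", derived=("B",), ancestor="A"
                    )
                ],
            )
        )
    priors = PriorSet(
        uniform={
            "NeA_small": (100.0, 200.0),
            "NeB_small": (100.0, 200.0),
            "NeA_big": (20_000.0, 30_000.0),
            "NeB_big": (20_000.0, 30_000.0),
            "t1": (100.0, 2000.0),
            "mu_mean": (5e-4, 5e-4),
            "p_mean": (0.2, 0.2),
        }
    )
    return ScenarioSet(scenarios=scenarios, priors=priors, loci=loci)


@pytest.fixture(scope="module")
def toy_table():
    ss = toy_scenario_set()
    table = build_reference_table(ss, 150, seed=3)
    return append_lda_axes(table)


@pytest.fixture(scope="module")
def small_table(scenario_set):
    table = build_reference_table(scenario_set, 40, seed=8)
    return append_lda_axes(table)


class TestReferenceTable:
    def test_row_and_feature_counts(self, small_table):
        assert small_table.stats.shape == (8 * 40, 130)
        assert len(small_table.feature_names) == 130

    def test_balanced_design(self, small_table):
        ids, counts = np.unique(small_table.scenario, return_counts=True)
        assert list(ids) == list(range(1, 9))
        assert np.all(counts == 40)

    def test_zero_rows_rejected(self, scenario_set):
        with pytest.raises(ValueError):
            build_reference_table(scenario_set, 0, seed=1)

    def test_same_seed_same_hash(self, scenario_set):
        a = build_reference_table(scenario_set, 5, seed=42)
        b = build_reference_table(scenario_set, 5, seed=42)
        assert a.table_hash() == b.table_hash()
        c = build_reference_table(scenario_set, 5, seed=43)
        assert a.table_hash() != c.table_hash()

    def test_round_trip_through_disk(self, toy_table, tmp_path):
        path = tmp_path / "rt.tsv"
        save_reference_table(toy_table, str(path))
        loaded = load_reference_table(str(path))
        np.testing.assert_allclose(loaded.stats, toy_table.stats, rtol=1e-6)
        assert np.array_equal(loaded.scenario, toy_table.scenario)

    def test_restrict_selects_single_scenario(self, toy_table):
        t1 = toy_table.restrict(1)
        assert set(np.unique(t1.scenario)) == {1}
        assert t1.n_rows == 150


class TestLdaAxes:
    def test_eight_scenarios_give_seven_axes(self, small_table):
        assert small_table.lda_scores.shape[1] == 7

    def test_two_scenarios_give_one_axis(self, toy_table):
        assert toy_table.lda_scores.shape[1] == 1

    def test_projection_matches_training_scores(self, toy_table):
        proj = toy_table.project_observed(toy_table.stats[17])
        np.testing.assert_allclose(proj[0], toy_table.lda_scores[17], atol=1e-8)


class TestScenarioChoice:
    def test_separable_toy_low_prior_error_high_votes(self, toy_table):
        ss = toy_scenario_set()
        held_out = build_reference_table(ss, 1, seed=777, scenario_ids=[1])
        res = scenario_choice(
            toy_table, held_out.stats[0], n_trees=300, seed=0, compute_posterior=True
        )
        assert res.prior_error < 0.05
        assert res.selected == 1
        assert res.votes[0] / res.votes.sum() > 0.9
        assert 0.0 <= res.posterior_probability <= 1.0

    def test_votes_sum_to_n_trees(self, small_table):
        res = scenario_choice(
            small_table, small_table.stats[0], n_trees=120, seed=1,
            compute_posterior=False,
        )
        assert res.votes.sum() == 120

    def test_permuted_labels_give_chance_error(self, scenario_set):
        """Random labels -> OOB error near 1 - 1/k. The discriminant axes
        are kept as fitted to the true labels (mere extra features here);
        refitting them on the permuted labels at a small table size would
        leak the permuted labels into the features."""
        base = append_lda_axes(build_reference_table(scenario_set, 150, seed=31))
        rng = np.random.default_rng(0)
        shuffled = ReferenceTable(
            stats=base.stats,
            scenario=rng.permutation(base.scenario),
            params=base.params,
            feature_names=base.feature_names,
            lda_scores=base.lda_scores,
            _lda=base._lda,
            _lda_cols=base._lda_cols,
        )
        res = scenario_choice(
            shuffled, shuffled.stats[0], n_trees=300, seed=2, compute_posterior=False
        )
        assert res.prior_error == pytest.approx(1 - 1 / 8, abs=0.05)

    def test_class_errors_average_to_global(self, toy_table):
        res = scenario_choice(
            toy_table, toy_table.stats[0], n_trees=200, seed=3, compute_posterior=False
        )
        weights = np.array([
            (toy_table.scenario == s).sum() for s in res.scenario_ids
        ])
        weighted = np.average(
            [res.class_errors[int(s)] for s in res.scenario_ids], weights=weights
        )
        assert weighted == pytest.approx(res.prior_error, abs=1e-6)

    def test_schema_mismatch_rejected(self, toy_table):
        with pytest.raises(ValueError, match="features"):
            scenario_choice(toy_table, np.zeros(7), n_trees=50)

    def test_prior_error_decreases_with_training_size(self):
        """More simulations per scenario cannot hurt the separable toy."""
        ss = toy_scenario_set()
        errors = []
        for n in (40, 120, 360):
            errs = []
            for seed in range(3):
                t = append_lda_axes(build_reference_table(ss, n, seed=50 + seed))
                r = scenario_choice(
                    t, t.stats[0], n_trees=150, seed=seed, compute_posterior=False
                )
                errs.append(r.prior_error)
            errors.append(np.mean(errs))
        assert errors[-1] <= errors[0] + 0.02


class TestParameterEstimation:
    def test_noiseless_feature_recovers_parameter(self):
        """A parameter duplicated as a feature gives near-zero NMAE and
        nominal interval coverage."""
        rng = np.random.default_rng(4)
        n = 1200
        y = rng.uniform(1000, 5000, size=n)
        X = np.column_stack([y, rng.normal(size=(n, 6))])
        table = ReferenceTable(
            stats=X,
            scenario=np.ones(n, dtype=np.int64),
            params=pd.DataFrame({"theta": y}),
            feature_names=[f"f{i}" for i in range(X.shape[1])],
        )
        est = estimate_parameters(
            table, X[0], ["theta"], n_trees=300, pls_axes=2, n_oob=400, seed=0
        )["theta"]
        assert est.global_nmae < 0.02
        assert est.coverage90 >= 0.85
        assert est.q05 <= est.median <= est.q95
        assert est.median == pytest.approx(y[0], rel=0.05)

    def test_quantile_ordering_enforced(self):
        from msatabc.abcrf import ParameterEstimate

        with pytest.raises(ValueError, match="ordering"):
            ParameterEstimate("x", 1.0, 2.0, 3.0, 1.0, 0.1, None, 0.9)

    def test_unknown_parameter_rejected(self, toy_table):
        t1 = toy_table.restrict(1)
        with pytest.raises(ValueError, match="absent"):
            estimate_parameters(t1, None, ["nonexistent"], n_trees=50)

    def test_multi_scenario_table_rejected(self, toy_table):
        with pytest.raises(ValueError, match="restrict"):
            estimate_parameters(toy_table, None, ["t1"], n_trees=50)


class TestReplication:
    def test_fresh_forests_vary_little_on_separable_toy(self, toy_table):
        obs = toy_table.stats[np.flatnonzero(toy_table.scenario == 1)[0]]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summary = replicate_analysis(
                toy_table, obs, n_replicates=4, seed=9,
                n_trees=200, compute_posterior=False,
            )
        votes_mean = summary.loc["votes_1", "mean"]
        votes_sd = summary.loc["votes_1", "std"]
        assert votes_sd < 0.2 * votes_mean

    def test_same_forest_seed_is_deterministic(self, toy_table):
        a = scenario_choice(toy_table, toy_table.stats[3], n_trees=100, seed=5)
        b = scenario_choice(toy_table, toy_table.stats[3], n_trees=100, seed=5)
        assert np.array_equal(a.votes, b.votes)
        assert a.prior_error == b.prior_error
        assert a.posterior_probability == b.posterior_probability
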