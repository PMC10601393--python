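"""Classical diversity and differentiation statistics for genotype tables.

Per-population diversity (mean alleles per locus A, private alleles Pa,
observed heterozygosity Ho, Nei's unbiased expected heterozygosity uHe,
hypergeometric rarefied allelic richness Ar, inbreeding coefficient Fis),
Weir–Cockerham F-statistics, maximum-likelihood null-allele frequencies
(EM under the null-allele model), null-corrected F_ST with the "excluding
null alleles" (ENA) adjustment and bootstrap CIs over loci, and
permutation tests for contrasts between groups of populations.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .containers import MISSING, GenotypeDataset

__all__ = [
    "DiversityReport",
    "FstReport",
    "NullAlleleEstimate",
    "basic_diversity",
    "allelic_richness",
    "wc_fstats",
    "null_allele_em",
    "fst_ena",
    "pairwise_fst_test",
    "group_permutation_test",
]


@dataclass
class DiversityReport:
    """Per-population diversity summary (arrays indexed like populations)."""

    populations: list[str]
    A: np.ndarray
    Pa: np.ndarray
    Ho: np.ndarray
    uHe: np.ndarray
    Fis: np.ndarray
    Ar: np.ndarray | None = None
    rarefaction_g: int | None = None


@dataclass
class FstReport:
    """Global and pairwise F_ST with optional ENA correction and CIs."""

    global_fst: float
    pairwise_fst: np.ndarray
    corrected: bool
    ci_level: float | None = None
    n_boot: int = 0
    global_ci: tuple[float, float] | None = None
    pairwise_ci: np.ndarray | None = None
    null_freqs: np.ndarray | None = None


@dataclass
class NullAlleleEstimate:
    """EM null-allele estimates per population × locus.

    ``visible_freqs[p][l]`` are the EM allele frequencies of the visible
    alleles (summing to ``1 − null_freq[p, l]``).
    """

    null_freq: np.ndarray
    visible_freqs: list[np.ndarray]
    iterations: np.ndarray
    converged: np.ndarray
    warnings: list[str] = field(default_factory=list)


# --------------------------------------------------------------------------
# helpers


def _pop_tables(ds: GenotypeDataset) -> tuple[list[np.ndarray], list[np.ndarray], int]:
    """Per-pop allele counts and heterozygote-carrier counts (+ max state)."""
    from .sumstats import _tables

    max_state = max(spec.window[1] for spec in ds.loci)
    obs_max = int(ds.genotypes.max()) if ds.genotypes.size else 0
    max_state = max(max_state, obs_max)
    counts, hets = [], []
    for i in range(ds.n_populations):
        c, h = _tables(ds.pop_genotypes(i), max_state)
        counts.append(c)
        hets.append(h)
    return counts, hets, max_state


def _ho_uhe(ds: GenotypeDataset, i: int) -> tuple[float, float]:
    """Mean over loci of observed and unbiased expected heterozygosity."""
    g = ds.pop_genotypes(i)
    ho_sum = uhe_sum = 0.0
    used = 0
    for l in range(ds.n_loci):
        a1, a2 = g[:, l, 0], g[:, l, 1]
        ok = (a1 != MISSING) & (a2 != MISSING)
        n = int(ok.sum())
        if n == 0:
            continue
        ho = float((a1[ok] != a2[ok]).mean())
        alleles = np.concatenate([a1[ok], a2[ok]]).astype(np.int64)
        c = np.bincount(alleles)
        copies = c.sum()
        p = c / copies
        if copies > 1:
            uhe = copies / (copies - 1.0) * (1.0 - float(p @ p))
        else:
            uhe = 0.0
        ho_sum += ho
        uhe_sum += uhe
        used += 1
    if used == 0:
        return np.nan, np.nan
    return ho_sum / used, uhe_sum / used


# --------------------------------------------------------------------------
# operations


def basic_diversity(ds: GenotypeDataset, rarefaction_g: int | None = None) -> DiversityReport:
    """A, Pa, Ho, uHe and Fis per population (optionally Ar at size g).

    A is the mean number of distinct alleles over loci; Pa counts alleles
    observed in exactly one population (over all loci); Ho is the mean
    fraction of heterozygous genotyped individuals; uHe the mean Nei
    unbiased gene diversity; Fis = 1 − Ho/uHe from the per-population
    means. Loci with no data in a population are excluded from that
    population's averages.
    """
    npop = ds.n_populations
    counts, _, _ = _pop_tables(ds)
    A = np.zeros(npop)
    Pa = np.zeros(npop, dtype=np.int64)
    Ho = np.zeros(npop)
    uHe = np.zeros(npop)
    Fis = np.zeros(npop)
    presence = [c > 0 for c in counts]
    total_presence = np.sum(np.stack([p.astype(int) for p in presence]), axis=0)
    for i in range(npop):
        per_locus_k = presence[i].sum(axis=1)
        informative = counts[i].sum(axis=1) > 0
        A[i] = per_locus_k[informative].mean() if informative.any() else np.nan
        Pa[i] = int((presence[i] & (total_presence == 1)).sum())
        Ho[i], uHe[i] = _ho_uhe(ds, i)
        Fis[i] = 1.0 - Ho[i] / uHe[i] if uHe[i] > 0 else np.nan
    report = DiversityReport(ds.populations, A=A, Pa=Pa, Ho=Ho, uHe=uHe, Fis=Fis)
    if rarefaction_g is not None:
        report.Ar = allelic_richness(ds, rarefaction_g)
        report.rarefaction_g = rarefaction_g
    return report


def allelic_richness(ds: GenotypeDataset, g: int | None = None) -> np.ndarray:
    """Rarefied allelic richness per population at ``g`` gene copies.

    Hypergeometric rarefaction: for a locus with n gene copies and allele
    counts n_a, the expected allele count in a subsample of g copies is
    ``sum_a (1 − C(n − n_a, g)/C(n, g))``; Ar is the average over loci.
    Defaults to the minimum genotyped gene-copy count over populations and
    loci (the FSTAT convention).
    """
    counts, _, _ = _pop_tables(ds)
    totals = np.stack([c.sum(axis=1) for c in counts])  # (npop, nloci)
    if g is None:
        g = int(totals.min())
    if g < 2:
        raise ValueError(f"rarefaction size g must be >= 2, got {g}")
    if g > totals.min():
        raise ValueError(
            f"g = {g} exceeds the smallest genotyped sample ({int(totals.min())} copies)"
        )

    def log_comb(n: np.ndarray, k: int) -> np.ndarray:
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    out = np.zeros(len(counts))
    for i, c in enumerate(counts):
        ar_sum = 0.0
        used = 0
        for l in range(c.shape[0]):
            n = c[l].sum()
            if n < g:
                continue
            na = c[l][c[l] > 0].astype(np.float64)
            keep = (n - na) >= g
            term = np.zeros_like(na)
            term[keep] = np.exp(log_comb(n - na[keep], g) - log_comb(float(n), g))
            ar_sum += float((1.0 - term).sum())
            used += 1
        out[i] = ar_sum / used if used else np.nan
    return out


def _wc_components(
    counts: list[np.ndarray],
    hets: list[np.ndarray],
    pops: list[int],
    sizes: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus Weir–Cockerham 'a' and 'a+b+c' sums over a set of pops.

    ``counts`` may be float (ENA-corrected pseudo-counts). ``sizes`` gives
    the genotyped diploid sample size per population × locus; by default it
    is inferred from the counts. Under the ENA correction the visible
    pseudo-counts sum to (1 − r)·2n while sizes stay at n, so the null
    class is excluded from the component sums without renormalisation.
    Components are summed over alleles within each locus so multi-locus
    estimates are ratios of summed components and loci can be
    bootstrap-resampled.
    """
    nl, S = counts[0].shape
    if sizes is None:
        sizes = np.stack([counts[p].sum(axis=1) / 2.0 for p in range(len(counts))])
    num = np.zeros(nl)
    den = np.zeros(nl)
    for l in range(nl):
        ns = np.array([float(sizes[p][l]) for p in pops])
        use = ns >= 1.0
        r = int(use.sum())
        if r < 2:
            num[l] = den[l] = np.nan
            continue
        idx = [p for p, u in zip(pops, use) if u]
        ns = ns[use]
        nbar = ns.mean()
        if nbar <= 1.0:
            num[l] = den[l] = np.nan
            continue
        nc = (r * nbar - (ns**2).sum() / (r * nbar)) / (r - 1.0)
        P = np.stack([
            counts[p][l] / (2.0 * sizes[p][l]) if sizes[p][l] > 0 else np.zeros(S)
            for p in idx
        ])
        H = np.stack([hets[p][l] / ns_i for p, ns_i in zip(idx, ns)])
        seen = P.sum(axis=0) > 0
        a_sum = d_sum = 0.0
        for a in np.flatnonzero(seen):
            pbar = float((ns * P[:, a]).sum() / (r * nbar))
            s2 = float((ns * (P[:, a] - pbar) ** 2).sum() / ((r - 1.0) * nbar))
            hbar = float((ns * H[:, a]).sum() / (r * nbar))
            a_comp = nbar / nc * (
                s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
            )
            b_comp = nbar / (nbar - 1.0) * (
                pbar * (1 - pbar) - (r - 1.0) / r * s2
                - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
            )
            c_comp = hbar / 2.0
            a_sum += a_comp
            d_sum += a_comp + b_comp + c_comp
        num[l] = a_sum
        den[l] = d_sum
    return num, den


def _ratio(num: np.ndarray, den: np.ndarray) -> float:
    ok = ~np.isnan(num)
    if not ok.any() or den[ok].sum() == 0:
        return np.nan
    return float(num[ok].sum() / den[ok].sum())


def wc_fstats(ds: GenotypeDataset) -> tuple[np.ndarray, float, np.ndarray]:
    """Per-population Fis, global F_ST and pairwise F_ST (Weir–Cockerham).

    Multi-locus estimates are ratios of variance components summed over
    loci and alleles. Returns ``(fis, global_fst, pairwise)`` with
    ``pairwise`` an (npop, npop) symmetric matrix (NaN diagonal).
    """
    npop = ds.n_populations
    if npop < 2:
        raise ValueError("F_ST requires >= 2 populations")
    counts, hets, _ = _pop_tables(ds)
    fis = basic_diversity(ds).Fis
    num, den = _wc_components(counts, hets, list(range(npop)))
    global_fst = _ratio(num, den)
    pairwise = np.full((npop, npop), np.nan)
    for i in range(npop):
        for j in range(i + 1, npop):
            nij, dij = _wc_components(counts, hets, [i, j])
            pairwise[i, j] = pairwise[j, i] = _ratio(nij, dij)
    return fis, global_fst, pairwise


def _null_loglik(
    hom_counts: np.ndarray,
    het_counts: np.ndarray,
    blanks: int,
    pvec: np.ndarray,
    r: float,
) -> float:
    """Multinomial log-likelihood of observed genotype classes under the
    null-allele model (apparent hom aa: p_a² + 2 p_a r; blank: r²)."""
    eps = 1e-300
    ll = 0.0
    hom_prob = pvec**2 + 2.0 * pvec * r
    m = hom_counts > 0
    ll += float((hom_counts[m] * np.log(hom_prob[m] + eps)).sum())
    m = het_counts > 0
    # het_counts stores allele incidences; each het genotype contributes
    # log(2 p_a p_b) = log 2 + log p_a + log p_b, so per-allele terms suffice
    ll += float((het_counts[m] * np.log(pvec[m] + eps)).sum())
    if blanks > 0:
        ll += blanks * 2.0 * np.log(r + eps)
    return ll


def null_allele_em(
    ds: GenotypeDataset,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    blanks_as_failures: bool = False,
) -> NullAlleleEstimate:
    """Maximum-likelihood null-allele frequencies per population × locus.

    EM under the null-allele model with Hardy–Weinberg genotype
    proportions: apparent homozygotes for allele a arise as true
    homozygotes (p_a²) or null heterozygotes (2 p_a r); fully blank
    genotypes are null homozygotes (r²). With ``blanks_as_failures`` blank
    genotypes are instead dropped (treated as technical failures) and the
    model conditions on a genotype being visible.
    """
    npop, nl = ds.n_populations, ds.n_loci
    _, _, max_state = _pop_tables(ds)
    null = np.zeros((npop, nl))
    iters = np.zeros((npop, nl), dtype=np.int64)
    conv = np.ones((npop, nl), dtype=bool)
    vis: list[np.ndarray] = []
    warn: list[str] = []
    for p in range(npop):
        g = ds.pop_genotypes(p)
        vfreq = np.zeros((nl, max_state + 1))
        for l in range(nl):
            a1 = g[:, l, 0].astype(np.int64)
            a2 = g[:, l, 1].astype(np.int64)
            visible = (a1 != MISSING) & (a2 != MISSING)
            blanks = int((~visible).sum())
            av1, av2 = a1[visible], a2[visible]
            n_vis = int(visible.sum())
            if n_vis == 0:
                if blanks > 0 and not blanks_as_failures:
                    null[p, l] = 1.0
                    warn.append(
                        f"pop {ds.populations[p]} locus {ds.loci[l].name}: all "
                        f"genotypes blank; null frequency set to 1"
                    )
                else:
                    null[p, l] = np.nan
                    conv[p, l] = False
                continue
            hom = av1 == av2
            hom_counts = np.bincount(av1[hom], minlength=max_state + 1).astype(float)
            het_counts = (
                np.bincount(av1[~hom], minlength=max_state + 1)
                + np.bincount(av2[~hom], minlength=max_state + 1)
            ).astype(float)
            if blanks_as_failures:
                blanks = 0
            N = n_vis + blanks
            # init: observed frequencies, small null
            c = hom_counts * 2 + het_counts
            pvec = c / c.sum()
            r = 0.05
            for it in range(max_iter):
                denom = pvec + 2.0 * r
                with np.errstate(divide="ignore", invalid="ignore"):
                    frac_true = np.where(denom > 0, pvec / denom, 0.0)
                true_hom = hom_counts * frac_true
                null_het = hom_counts - true_hom
                new_counts = 2.0 * true_hom + het_counts + null_het
                null_count = null_het.sum() + 2.0 * blanks
                total = 2.0 * N
                new_p = new_counts / total
                new_r = null_count / total
                delta = max(float(np.abs(new_p - pvec).max()), abs(new_r - r))
                pvec, r = new_p, new_r
                if delta < tol:
                    iters[p, l] = it + 1
                    break
            else:
                iters[p, l] = max_iter
                conv[p, l] = False
                warn.append(
                    f"pop {ds.populations[p]} locus {ds.loci[l].name}: EM did not "
                    f"converge in {max_iter} iterations (last delta {delta:.2e})"
                )
            # EM approaches the r = 0 boundary only sublinearly (the map is
            # r <- r(1-r) for null-free data); compare the likelihood at the
            # boundary and snap to the global maximum when it wins
            if blanks == 0:
                p0 = c / c.sum()
                if _null_loglik(hom_counts, het_counts, 0, p0, 0.0) >= _null_loglik(
                    hom_counts, het_counts, 0, pvec, r
                ):
                    pvec, r = p0, 0.0
            null[p, l] = r
            vfreq[l] = pvec
        vis.append(vfreq)
    return NullAlleleEstimate(null, vis, iters, conv, warn)


def fst_ena(
    ds: GenotypeDataset,
    null_freqs: np.ndarray | NullAlleleEstimate | None = None,
    n_boot: int = 10_000,
    seed: int | None = 0,
    ci_level: float = 0.95,
) -> FstReport:
    """F_ST with the "excluding null alleles" (ENA) correction.

    The null allele is treated as an extra allelic state: visible allele
    frequencies are the EM estimates (summing to 1 − r), and the null class
    is excluded from the variance-component sums. With all null
    frequencies zero this reduces exactly to the uncorrected
    Weir–Cockerham estimate. Percentile bootstrap CIs resample loci.
    """
    npop, nl = ds.n_populations, ds.n_loci
    counts, hets, max_state = _pop_tables(ds)
    if null_freqs is None:
        null_freqs = null_allele_em(ds)
    if isinstance(null_freqs, NullAlleleEstimate):
        est = null_freqs
        null = np.nan_to_num(est.null_freq)
        corr_counts = []
        for p in range(npop):
            tot = counts[p].sum(axis=1, keepdims=True).astype(float)
            corr = est.visible_freqs[p] * tot
            # loci the EM skipped fall back to observed counts
            bad = est.visible_freqs[p].sum(axis=1) == 0
            corr[bad] = counts[p][bad]
            corr_counts.append(corr)
        vis_freqs = [est.visible_freqs[p] for p in range(npop)]
    else:
        null = np.asarray(null_freqs, dtype=float)
        if null.shape != (npop, nl):
            raise ValueError(f"null_freqs must have shape ({npop}, {nl})")
        corr_counts = [
            counts[p] * (1.0 - null[p])[:, None] for p in range(npop)
        ]
        vis_freqs = [
            np.divide(
                corr_counts[p],
                np.maximum(counts[p].sum(axis=1, keepdims=True), 1),
            )
            for p in range(npop)
        ]
    # apparent homozygotes hiding a null are heterozygous for their visible
    # allele (the partner allele is the excluded null state): add their
    # expected count back to the per-allele heterozygote tables. The term
    # vanishes at r = 0, so the zero-null reduction stays exact.
    corr_hets = []
    for p in range(npop):
        hom = (counts[p] - hets[p]) / 2.0  # homozygous individuals per allele
        r = null[p][:, None]
        pa = vis_freqs[p]
        with np.errstate(divide="ignore", invalid="ignore"):
            null_het = np.where(pa + 2 * r > 0, hom * 2 * r / (pa + 2 * r), 0.0)
        corr_hets.append(hets[p] + null_het)

    sizes = np.stack([counts[p].sum(axis=1) / 2.0 for p in range(npop)])
    num, den = _wc_components(corr_counts, corr_hets, list(range(npop)), sizes=sizes)
    global_fst = _ratio(num, den)
    pair_nums = {}
    pairwise = np.full((npop, npop), np.nan)
    for i in range(npop):
        for j in range(i + 1, npop):
            nij, dij = _wc_components(corr_counts, corr_hets, [i, j], sizes=sizes)
            pair_nums[(i, j)] = (nij, dij)
            pairwise[i, j] = pairwise[j, i] = _ratio(nij, dij)

    report = FstReport(
        global_fst=global_fst,
        pairwise_fst=pairwise,
        corrected=bool(np.any(null > 0)),
        null_freqs=null,
    )
    if n_boot > 0:
        if nl < 2:
            import warnings as _w

            _w.warn("bootstrap CI over a single locus is degenerate")
        rng = np.random.default_rng(seed)
        alpha = (1.0 - ci_level) / 2.0
        idx = rng.integers(0, nl, size=(n_boot, nl))
        reps = np.array([_ratio(num[ix], den[ix]) for ix in idx])
        reps = reps[~np.isnan(reps)]
        if reps.size:
            report.global_ci = (
                float(np.quantile(reps, alpha)),
                float(np.quantile(reps, 1 - alpha)),
            )
        pair_ci = np.full((npop, npop, 2), np.nan)
        for (i, j), (nij, dij) in pair_nums.items():
            reps = np.array([_ratio(nij[ix], dij[ix]) for ix in idx])
            reps = reps[~np.isnan(reps)]
            if reps.size:
                pair_ci[i, j] = pair_ci[j, i] = (
                    np.quantile(reps, alpha),
                    np.quantile(reps, 1 - alpha),
                )
        report.pairwise_ci = pair_ci
        report.ci_level = ci_level
        report.n_boot = n_boot
    return report


def pairwise_fst_test(
    ds: GenotypeDataset,
    i: int,
    j: int,
    n_perm: int = 9_999,
    seed: int | None = 0,
) -> tuple[float, float]:
    """Permutation significance of the pairwise F_ST between populations
    ``i`` and ``j``: individuals are shuffled between the two samples and
    the one-sided p-value is (1 + #{perm >= observed})/(n_perm + 1)."""
    if i == j:
        raise ValueError("need two distinct populations")
    gi = ds.pop_genotypes(i)
    gj = ds.pop_genotypes(j)
    from .sumstats import _tables, _wc_pair_core

    max_state = max(spec.window[1] for spec in ds.loci)
    max_state = max(max_state, int(ds.genotypes.max()) if ds.genotypes.size else 0)

    def fst(a: np.ndarray, b: np.ndarray) -> float:
        ca, ha = _tables(np.ascontiguousarray(a), max_state)
        cb, hb = _tables(np.ascontiguousarray(b), max_state)
        num, den = _wc_pair_core(ca, cb, ha, hb)
        return num / den if den != 0.0 else np.nan

    observed = fst(gi, gj)
    pool = np.concatenate([gi, gj], axis=0)
    ni = gi.shape[0]
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pool.shape[0])
        d = fst(pool[perm[:ni]], pool[perm[ni:]])
        if not np.isnan(d) and d >= observed - 1e-15:
            hits += 1
    return float(observed), (1.0 + hits) / (n_perm + 1.0)


_GROUP_STATS = ("He", "Ar", "Fis", "Fst")


def _group_value(
    ds: GenotypeDataset,
    pops: list[int],
    statistic: str,
    counts: list[np.ndarray],
    hets: list[np.ndarray],
    per_pop: np.ndarray | None,
) -> float:
    if statistic == "Fst":
        if len(pops) < 2:
            return np.nan
        num, den = _wc_components(counts, hets, pops)
        return _ratio(num, den)
    return float(np.nanmean(per_pop[pops]))


def group_permutation_test(
    ds: GenotypeDataset,
    grouping: dict[str, list[int]],
    statistic: str,
    n_perm: int = 9_999,
    seed: int | None = 0,
) -> tuple[float, float]:
    """Permutation test for a difference in a statistic between population groups.

    ``grouping`` maps group labels to population indices (two groups).
    The observed statistic is the difference of group values (mean per-pop
    He/Ar/Fis, or the within-group multi-pop F_ST); whole populations are
    permuted between groups and the two-sided p-value is
    ``(1 + #{|perm| >= |obs|}) / (n_perm + 1)``.
    """
    if statistic not in _GROUP_STATS:
        raise ValueError(f"statistic must be one of {_GROUP_STATS}")
    groups = list(grouping.values())
    if len(groups) != 2:
        raise ValueError("exactly two groups of populations are required")
    if any(len(g) == 0 for g in groups):
        raise ValueError("each group needs at least one population")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    counts, hets, _ = _pop_tables(ds)
    per_pop = None
    if statistic == "He":
        per_pop = basic_diversity(ds).uHe
    elif statistic == "Ar":
        per_pop = allelic_richness(ds)
    elif statistic == "Fis":
        per_pop = basic_diversity(ds).Fis

    def diff(g1: list[int], g2: list[int]) -> float:
        return _group_value(ds, g1, statistic, counts, hets, per_pop) - _group_value(
            ds, g2, statistic, counts, hets, per_pop
        )

    observed = diff(groups[0], groups[1])
    all_pops = np.array(groups[0] + groups[1])
    n1 = len(groups[0])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(all_pops)
        d = diff(list(perm[:n1]), list(perm[n1:]))
        if abs(d) >= abs(observed) - 1e-15:
            hits += 1
    p = (1.0 + hits) / (n_perm + 1.0)
    return float(observed), float(p)
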