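"""Microsatellite summary statistics: the ABC feature vector.

For ``n`` populations the vector concatenates, in a fixed documented order:

* one-sample (4·n): NAL (mean number of alleles per locus), HET (mean
  unbiased genic diversity), VAR (mean allele-size variance), MGW (mean
  Garza–Williamson ratio k/(R+1)), each averaged over loci — grouped by
  statistic, populations in dataset order;
* two-sample, unordered pairs i<j (6·C(n,2)): NAL2/HET2/VAR2 on the pooled
  pair, FST (Weir–Cockerham, components summed over loci), DAS
  (shared-allele distance) and DM2 (δµ², squared difference of mean allele
  size), grouped by statistic;
* directed pairs (2·C(n,2)): LIK i→j, the mean over individuals of i of the
  log-likelihood of their multilocus genotype under j's allele frequencies,
  in order (0→1, 1→0, 0→2, 2→0, ...);
* admixture triples (n·C(n−1,2)): AML, the maximum-likelihood admixture
  proportion of a target population between an unordered parent pair,
  ordered by target then parent pair.

For five populations this is exactly 130 features. The per-locus kernels
are numba-compiled so that reference-table construction stays tractable.
"""
from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
from numba import njit

from .containers import MISSING, GenotypeDataset

__all__ = [
    "one_sample_stats",
    "two_sample_stats",
    "three_sample_admixture",
    "summarize_dataset",
    "feature_names",
    "n_features",
]


class DegenerateDataError(ValueError):
    """Raised when no locus carries enough data to compute a statistic."""


def n_features(n_pops: int) -> int:
    """Length of the feature vector for ``n_pops`` populations."""
    npairs = n_pops * (n_pops - 1) // 2
    ntriples = n_pops * (n_pops - 1) * (n_pops - 2) // 2
    return 4 * n_pops + 6 * npairs + 2 * npairs + ntriples


def feature_names(populations: list[str]) -> list[str]:
    """Ordered names matching :func:`summarize_dataset` output."""
    n = len(populations)
    names: list[str] = []
    for stat in ("NAL", "HET", "VAR", "MGW"):
        names += [f"{stat}_{p}" for p in populations]
    pairs = list(combinations(range(n), 2))
    for stat in ("NAL2", "HET2", "VAR2", "FST", "DAS", "DM2"):
        names += [f"{stat}_{populations[i]}_{populations[j]}" for i, j in pairs]
    for i, j in pairs:
        names += [f"LIK_{populations[i]}_{populations[j]}",
                  f"LIK_{populations[j]}_{populations[i]}"]
    for t in range(n):
        for i, j in combinations([x for x in range(n) if x != t], 2):
            names.append(f"AML_{populations[t]}_{populations[i]}_{populations[j]}")
    return names


# --------------------------------------------------------------------------
# compiled per-locus kernels


@njit(cache=True)
def _tables_core(g, max_state):  # pragma: no cover - via wrappers
    """Allele counts and heterozygote-carrier counts per locus and state."""
    n, nl = g.shape[0], g.shape[1]
    counts = np.zeros((nl, max_state + 1), np.int64)
    hets = np.zeros((nl, max_state + 1), np.int64)
    for l in range(nl):
        for i in range(n):
            a1 = g[i, l, 0]
            a2 = g[i, l, 1]
            if a1 >= 0:
                counts[l, a1] += 1
            if a2 >= 0:
                counts[l, a2] += 1
            if a1 >= 0 and a2 >= 0 and a1 != a2:
                hets[l, a1] += 1
                hets[l, a2] += 1
    return counts, hets


@njit(cache=True)
def _one_sample_core(counts):  # pragma: no cover - via wrappers
    """(NAL, HET, VAR, MGW, n_loci_used) averaged over informative loci."""
    nl, S = counts.shape
    nal = het = var = mgw = 0.0
    used = 0
    for l in range(nl):
        n = 0
        k = 0
        first = -1
        last = -1
        mean = 0.0
        for a in range(S):
            c = counts[l, a]
            if c > 0:
                n += c
                k += 1
                last = a
                if first < 0:
                    first = a
                mean += c * a
        if n < 2:
            continue
        mean /= n
        sumsq = 0.0
        sump2 = 0.0
        for a in range(S):
            c = counts[l, a]
            if c > 0:
                sumsq += c * (a - mean) ** 2
                p = c / n
                sump2 += p * p
        nal += k
        het += n / (n - 1.0) * (1.0 - sump2)
        var += sumsq / (n - 1.0)
        mgw += k / (last - first + 1.0)
        used += 1
    if used > 0:
        return nal / used, het / used, var / used, mgw / used, used
    return np.nan, np.nan, np.nan, np.nan, 0


@njit(cache=True)
def _wc_pair_core(cA, cB, hetA, hetB):  # pragma: no cover - via wrappers
    """Weir–Cockerham FST variance components summed over loci and alleles.

    ``het*`` count heterozygous *individuals* carrying each allele. Returns
    (numerator, denominator); the estimate is their ratio.
    """
    nl, S = cA.shape
    num = 0.0
    den = 0.0
    r = 2.0
    for l in range(nl):
        totA = 0
        totB = 0
        k = 0
        for a in range(S):
            totA += cA[l, a]
            totB += cB[l, a]
            if cA[l, a] + cB[l, a] > 0:
                k += 1
        nA = totA / 2.0
        nB = totB / 2.0
        if nA < 1.0 or nB < 1.0 or k < 2:
            continue
        nbar = (nA + nB) / r
        if nbar <= 1.0:
            continue
        nc = (r * nbar - (nA * nA + nB * nB) / (r * nbar)) / (r - 1.0)
        for a in range(S):
            if cA[l, a] + cB[l, a] == 0:
                continue
            pA = cA[l, a] / (2.0 * nA)
            pB = cB[l, a] / (2.0 * nB)
            pbar = (nA * pA + nB * pB) / (r * nbar)
            s2 = (nA * (pA - pbar) ** 2 + nB * (pB - pbar) ** 2) / ((r - 1.0) * nbar)
            hbar = (hetA[l, a] + hetB[l, a]) / (r * nbar)
            a_comp = nbar / nc * (
                s2 - (pbar * (1.0 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
            )
            b_comp = nbar / (nbar - 1.0) * (
                pbar * (1.0 - pbar) - (r - 1.0) / r * s2
                - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
            )
            c_comp = hbar / 2.0
            num += a_comp
            den += a_comp + b_comp + c_comp
    return num, den


@njit(cache=True)
def _das_core(ga, gb):  # pragma: no cover - via wrappers
    """Shared-allele distance: 1 − mean shared-allele proportion over
    inter-population individual pairs (alleles shared 0/0.5/1 per locus)."""
    na, nl = ga.shape[0], ga.shape[1]
    nb = gb.shape[0]
    tot = 0.0
    npairs = 0.0
    for i in range(na):
        for j in range(nb):
            s = 0.0
            nloc = 0
            for l in range(nl):
                a1, a2 = ga[i, l, 0], ga[i, l, 1]
                b1, b2 = gb[j, l, 0], gb[j, l, 1]
                if a1 < 0 or a2 < 0 or b1 < 0 or b2 < 0:
                    continue
                # multiset intersection size of {a1,a2} and {b1,b2}
                if a1 == b1:
                    m = 2 if a2 == b2 else 1
                elif a1 == b2:
                    m = 2 if a2 == b1 else 1
                elif a2 == b1 or a2 == b2:
                    m = 1
                else:
                    m = 0
                s += m / 2.0
                nloc += 1
            if nloc > 0:
                tot += s / nloc
                npairs += 1.0
    if npairs == 0:
        return np.nan
    return 1.0 - tot / npairs


@njit(cache=True)
def _lik_core(g_from, counts_to):  # pragma: no cover - via wrappers
    """Mean multilocus genotype log-likelihood of ``g_from`` individuals
    under the allele frequencies implied by ``counts_to``.

    Unseen alleles are floored at frequency 1/(2n + k), n the scored
    population's diploid size and k its allele count at the locus.
    """
    n, nl = g_from.shape[0], g_from.shape[1]
    S = counts_to.shape[1]
    freqs = np.empty((nl, S), np.float64)
    for l in range(nl):
        tot = 0
        k = 0
        for a in range(S):
            tot += counts_to[l, a]
            if counts_to[l, a] > 0:
                k += 1
        if tot == 0:
            for a in range(S):
                freqs[l, a] = 1.0
            continue
        floor = 1.0 / (tot + k)
        for a in range(S):
            c = counts_to[l, a]
            freqs[l, a] = c / tot if c > 0 else floor
    total = 0.0
    scored = 0
    for i in range(n):
        ll = 0.0
        valid = 0
        for l in range(nl):
            a1 = g_from[i, l, 0]
            a2 = g_from[i, l, 1]
            if a1 < 0 or a2 < 0:
                continue
            if a1 == a2:
                ll += np.log(freqs[l, a1] * freqs[l, a2])
            else:
                ll += np.log(2.0 * freqs[l, a1] * freqs[l, a2])
            valid += 1
        if valid > 0:
            total += ll
            scored += 1
    if scored == 0:
        return np.nan
    return total / scored


@njit(cache=True)
def _dm2_core(cA, cB):  # pragma: no cover - via wrappers
    """Mean over loci of squared difference of mean allele size (δµ²)."""
    nl, S = cA.shape
    tot = 0.0
    used = 0
    for l in range(nl):
        nA = 0
        nB = 0
        mA = 0.0
        mB = 0.0
        for a in range(S):
            nA += cA[l, a]
            nB += cB[l, a]
            mA += cA[l, a] * a
            mB += cB[l, a] * a
        if nA == 0 or nB == 0:
            continue
        d = mA / nA - mB / nB
        tot += d * d
        used += 1
    if used == 0:
        return np.nan
    return tot / used


@njit(cache=True)
def _aml_core(counts_t, counts_p1, counts_p2, tol):  # pragma: no cover
    """Golden-section maximiser of the admixture multinomial likelihood.

    Returns the ML proportion contributed by parent 1, or -1.0 when the
    parents' frequencies are indistinguishable (flat likelihood).
    """
    nl, S = counts_t.shape
    f1 = np.zeros((nl, S), np.float64)
    f2 = np.zeros((nl, S), np.float64)
    same = True
    for l in range(nl):
        t1 = 0
        t2 = 0
        for a in range(S):
            t1 += counts_p1[l, a]
            t2 += counts_p2[l, a]
        for a in range(S):
            if t1 > 0:
                f1[l, a] = counts_p1[l, a] / t1
            if t2 > 0:
                f2[l, a] = counts_p2[l, a] / t2
            if same and abs(f1[l, a] - f2[l, a]) > 1e-12:
                same = False
    if same:
        return -1.0
    eps = 1e-12

    def negll(x, counts_t, f1, f2):
        s = 0.0
        nl, S = counts_t.shape
        for l in range(nl):
            for a in range(S):
                c = counts_t[l, a]
                if c > 0:
                    mix = x * f1[l, a] + (1.0 - x) * f2[l, a]
                    if mix < eps:
                        mix = eps
                    s -= c * np.log(mix)
        return s

    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    lo, hi = 0.0, 1.0
    x1 = hi - invphi * (hi - lo)
    x2 = lo + invphi * (hi - lo)
    v1 = negll(x1, counts_t, f1, f2)
    v2 = negll(x2, counts_t, f1, f2)
    while hi - lo > tol:
        if v1 < v2:
            hi, x2, v2 = x2, x1, v1
            x1 = hi - invphi * (hi - lo)
            v1 = negll(x1, counts_t, f1, f2)
        else:
            lo, x1, v1 = x1, x2, v2
            x2 = lo + invphi * (hi - lo)
            v2 = negll(x2, counts_t, f1, f2)
    best = 0.5 * (lo + hi)
    bestv = negll(best, counts_t, f1, f2)
    # pure-parent targets maximise at the boundary
    for cand in (lo, hi, 0.0, 1.0):
        v = negll(cand, counts_t, f1, f2)
        if v < bestv:
            best = cand
            bestv = v
    return best


# --------------------------------------------------------------------------
# public operations


def _tables(g: np.ndarray, max_state: int) -> tuple[np.ndarray, np.ndarray]:
    return _tables_core(np.ascontiguousarray(g), max_state)


def one_sample_stats(
    genotypes: np.ndarray, max_state: int | None = None
) -> tuple[float, float, float, float]:
    """NAL, HET, VAR, MGW for one population's genotype block.

    ``genotypes`` has shape (n_individuals, n_loci, 2); loci with fewer than
    two non-missing gene copies are skipped in the per-locus average.
    """
    if max_state is None:
        max_state = int(genotypes.max()) if genotypes.size else 1
    counts, _ = _tables(genotypes, max_state)
    nal, het, var, mgw, used = _one_sample_core(counts)
    if used == 0:
        raise DegenerateDataError("no locus with >= 2 gene copies")
    return nal, het, var, mgw


def two_sample_stats(
    gA: np.ndarray, gB: np.ndarray, max_state: int | None = None
) -> dict[str, float]:
    """Pairwise statistics for two population genotype blocks.

    Returns NAL2/HET2/VAR2 (one-sample statistics on the pooled sample),
    FST (Weir–Cockerham), DAS, DM2 and the two directed LIK values
    (``LIK_AB`` scores A's individuals against B's frequencies).
    """
    if gA.shape[0] == 0 or gB.shape[0] == 0:
        raise ValueError("two_sample_stats requires non-empty populations")
    if max_state is None:
        max_state = int(max(gA.max(), gB.max()))
    cA, hA = _tables(gA, max_state)
    cB, hB = _tables(gB, max_state)
    nal2, het2, var2, _, used = _one_sample_core(cA + cB)
    if used == 0:
        raise DegenerateDataError("no locus with >= 2 pooled gene copies")
    num, den = _wc_pair_core(cA, cB, hA, hB)
    return {
        "NAL2": nal2,
        "HET2": het2,
        "VAR2": var2,
        "FST": num / den if den != 0.0 else np.nan,
        "DAS": float(_das_core(np.ascontiguousarray(gA), np.ascontiguousarray(gB))),
        "DM2": float(_dm2_core(cA, cB)),
        "LIK_AB": float(_lik_core(np.ascontiguousarray(gA), cB)),
        "LIK_BA": float(_lik_core(np.ascontiguousarray(gB), cA)),
    }


def three_sample_admixture(
    counts_t: np.ndarray,
    counts_p1: np.ndarray,
    counts_p2: np.ndarray,
    tol: float = 1e-4,
) -> float:
    """ML admixture coefficient of a target between two parent populations.

    Inputs are per-locus allele count tables (n_loci × states). Maximises
    the multinomial log-likelihood of the target's counts under mixture
    frequencies ``a·p1 + (1−a)·p2`` by golden-section search on [0, 1] (the
    log-likelihood is concave in ``a``). Returns 0.5 with a warning when
    the parents are indistinguishable.
    """
    a = _aml_core(
        counts_t.astype(np.int64), counts_p1.astype(np.int64),
        counts_p2.astype(np.int64), tol,
    )
    if a < 0.0:
        warnings.warn("admixture parents have identical frequencies; AML undefined")
        return 0.5
    return float(a)


def summarize_dataset(dataset: GenotypeDataset, tol_aml: float = 1e-4) -> np.ndarray:
    """Compute the full ordered feature vector for a dataset.

    See the module docstring for the ordering; for five populations the
    result has exactly 130 entries.
    """
    n = dataset.n_populations
    if n < 2:
        raise ValueError("summary vector requires >= 2 populations")
    max_state = max(spec.window[1] for spec in dataset.loci)
    blocks = [np.ascontiguousarray(dataset.pop_genotypes(i)) for i in range(n)]
    tables = [_tables(b, max_state) for b in blocks]
    counts = [t[0] for t in tables]
    hets = [t[1] for t in tables]

    feats: list[float] = []
    one = []
    for i in range(n):
        nal, het, var, mgw, used = _one_sample_core(counts[i])
        if used == 0:
            raise DegenerateDataError(
                f"population {dataset.populations[i]}: no informative locus"
            )
        one.append((nal, het, var, mgw))
    for s in range(4):
        feats += [one[i][s] for i in range(n)]

    pairs = list(combinations(range(n), 2))
    pooled: dict[str, list[float]] = {
        k: [] for k in ("NAL2", "HET2", "VAR2", "FST", "DAS", "DM2")
    }
    for i, j in pairs:
        nal2, het2, var2, _, _ = _one_sample_core(counts[i] + counts[j])
        num, den = _wc_pair_core(counts[i], counts[j], hets[i], hets[j])
        pooled["NAL2"].append(nal2)
        pooled["HET2"].append(het2)
        pooled["VAR2"].append(var2)
        pooled["FST"].append(num / den if den != 0.0 else np.nan)
        pooled["DAS"].append(float(_das_core(blocks[i], blocks[j])))
        pooled["DM2"].append(float(_dm2_core(counts[i], counts[j])))
    for k in ("NAL2", "HET2", "VAR2", "FST", "DAS", "DM2"):
        feats += pooled[k]
    for i, j in pairs:
        feats.append(float(_lik_core(blocks[i], counts[j])))
        feats.append(float(_lik_core(blocks[j], counts[i])))

    for t in range(n):
        others = [x for x in range(n) if x != t]
        for i, j in combinations(others, 2):
            a = _aml_core(counts[t], counts[i], counts[j], tol_aml)
            feats.append(0.5 if a < 0.0 else float(a))

    out = np.asarray(feats, dtype=np.float64)
    expected = n_features(n)
    assert out.size == expected, f"feature count {out.size} != {expected}"
    if not np.isfinite(out).all():
        # a comparison with no informative locus anywhere (e.g. FST on a
        # fully monomorphic pair) yields NaN; replace with a sentinel
        bad = [feature_names(dataset.populations)[i] for i in np.flatnonzero(~np.isfinite(out))]
        warnings.warn(f"degenerate summary statistics set to 0: {bad}")
        out = np.nan_to_num(out, nan=0.0, posinf=0.0, neginf=0.0)
    return out
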