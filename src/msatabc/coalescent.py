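"""Backward-time coalescent simulation of microsatellite genotypes.

Within each constant-size population, lineage pairs coalesce at rate
1/(2Ne) per generation; exponential waiting times run between the
scenario's fixed event times. A split event moves the derived populations'
lineages into the ancestor; an admixture event sends each target lineage to
the first source with probability ``ra``. Once the genealogy is built,
mutations are laid down as a Poisson process at the locus rate per branch
generation under a generalized stepwise model: each mutation shifts the
repeat count by ±s with s geometric, Pr(s = k) = (1 − P) P^(k−1), sign
equiprobable; P = 0 is the strict stepwise model. Repeat counts leaving the
locus's allowed window are reflected at the boundary.

The simulation core is numba-compiled; per-locus substreams are derived
deterministically from the dataset seed, so adding loci never perturbs
earlier ones.
"""
from __future__ import annotations

import numpy as np
from numba import njit

from .containers import MISSING, GenotypeDataset, LocusSpec
from .scenarios import DemographicScenario, ParameterDraw

__all__ = ["simulate_locus", "simulate_dataset"]


@njit(cache=True)
def _sim_locus_core(
    seed,
    sample_copies,
    ne,
    ev_time,
    ev_kind,
    ev_a,
    ev_b,
    ev_c,
    ev_ra,
    mu,
    p_geom,
    anc_state,
    lo,
    hi,
):  # pragma: no cover - exercised through simulate_locus
    np.random.seed(seed)
    npop = len(ne)
    total = 0
    for p in range(npop):
        total += sample_copies[p]
    if total == 0:
        return np.empty(0, np.int64), 0.0
    n_nodes = 2 * total - 1
    parent = np.full(n_nodes, -1, np.int64)
    ntime = np.zeros(n_nodes, np.float64)
    act = np.empty((npop, total), np.int64)
    cnt = np.zeros(npop, np.int64)
    nid = 0
    for p in range(npop):
        for _ in range(sample_copies[p]):
            act[p, cnt[p]] = nid
            cnt[p] += 1
            nid += 1
    t = 0.0
    iev = 0
    nev = len(ev_time)
    nactive = total
    while nactive > 1:
        rate = 0.0
        for p in range(npop):
            k = cnt[p]
            if k > 1:
                rate += k * (k - 1) / 2.0 / (2.0 * ne[p])
        if rate > 0.0:
            wait = np.random.exponential(1.0 / rate)
        else:
            wait = np.inf
        if iev < nev and (rate == 0.0 or t + wait >= ev_time[iev]):
            t = ev_time[iev]
            if ev_kind[iev] == 0:
                a = ev_a[iev]
                b = ev_b[iev]
                for i in range(cnt[a]):
                    act[b, cnt[b]] = act[a, i]
                    cnt[b] += 1
                cnt[a] = 0
            else:
                a = ev_a[iev]
                b = ev_b[iev]
                c = ev_c[iev]
                ra = ev_ra[iev]
                for i in range(cnt[a]):
                    if np.random.random() < ra:
                        act[b, cnt[b]] = act[a, i]
                        cnt[b] += 1
                    else:
                        act[c, cnt[c]] = act[a, i]
                        cnt[c] += 1
                cnt[a] = 0
            iev += 1
            continue
        if rate == 0.0:
            # lineages stranded in disconnected populations
            return np.full(total, -1, np.int64), -1.0
        t += wait
        u = np.random.random() * rate
        acc = 0.0
        pp = 0
        for p in range(npop):
            k = cnt[p]
            if k > 1:
                acc += k * (k - 1) / 2.0 / (2.0 * ne[p])
                if u < acc:
                    pp = p
                    break
        k = cnt[pp]
        i = np.random.randint(0, k)
        j = np.random.randint(0, k - 1)
        if j >= i:
            j += 1
        ni = act[pp, i]
        nj = act[pp, j]
        newn = nid
        nid += 1
        parent[ni] = newn
        parent[nj] = newn
        ntime[newn] = t
        act[pp, i] = newn
        act[pp, j] = act[pp, k - 1]
        cnt[pp] = k - 1
        nactive -= 1
    # mutations, parents before children (node ids increase with time)
    state = np.empty(n_nodes, np.int64)
    root = nid - 1
    tmrca = ntime[root]
    state[root] = anc_state
    for node in range(root - 1, -1, -1):
        pa = parent[node]
        blen = ntime[pa] - ntime[node]
        s = state[pa]
        nmut = np.random.poisson(mu * blen)
        for _ in range(nmut):
            if p_geom > 0.0:
                step = np.random.geometric(1.0 - p_geom)
            else:
                step = 1
            if np.random.random() < 0.5:
                s += step
            else:
                s -= step
            while s < lo or s > hi:
                if s > hi:
                    s = 2 * hi - s
                if s < lo:
                    s = 2 * lo - s
        state[node] = s
    return state[:total], tmrca


def _encode_events(
    scenario: DemographicScenario, draw: ParameterDraw, pop_index: dict[str, int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Flatten the scenario's events into arrays sorted by drawn time.

    Splits with several derived lineages expand into one row per derived
    population (same time). Admixture proportions are clipped to [0, 1].
    """
    rows: list[tuple[float, int, int, int, int, float]] = []
    for ev in scenario.events:
        t = draw.values[ev.time_param]
        if t <= 0:
            raise ValueError(f"event time {ev.time_param} must be positive, got {t}")
        if ev.kind == "split":
            for d in ev.derived:
                rows.append((t, 0, pop_index[d], pop_index[ev.ancestor], -1, 0.0))
        else:
            ra = min(max(draw.values[ev.ra_param], 0.0), 1.0)
            rows.append(
                (t, 1, pop_index[ev.target], pop_index[ev.source1], pop_index[ev.source2], ra)
            )
    rows.sort(key=lambda r: r[0])
    ev_time = np.array([r[0] for r in rows], np.float64)
    ev_kind = np.array([r[1] for r in rows], np.int64)
    ev_a = np.array([r[2] for r in rows], np.int64)
    ev_b = np.array([r[3] for r in rows], np.int64)
    ev_c = np.array([r[4] for r in rows], np.int64)
    ev_ra = np.array([r[5] for r in rows], np.float64)
    return ev_time, ev_kind, ev_a, ev_b, ev_c, ev_ra


def _check_draw(scenario: DemographicScenario, draw: ParameterDraw) -> None:
    if draw.scenario_id != scenario.id:
        raise ValueError(
            f"draw belongs to scenario {draw.scenario_id}, not {scenario.id}"
        )
    missing = [p for p in scenario.param_names() if p not in draw.values]
    if missing:
        raise ValueError(f"draw lacks parameters {missing}")


def simulate_locus(
    scenario: DemographicScenario,
    draw: ParameterDraw,
    locus: LocusSpec,
    rng: np.random.Generator,
    mu: float | None = None,
    p_geom: float | None = None,
    return_tmrca: bool = False,
) -> np.ndarray:
    """Simulate allele sizes for every sampled gene copy at one locus.

    Returns an int array of length 2 × total diploid sample size, ordered by
    population then copy (with ``return_tmrca`` also the time to the most
    recent common ancestor in generations). ``mu``/``p_geom`` override the
    per-locus draw (useful for single-locus experiments); by default the
    first entries of ``draw.mu_l``/``draw.p_l`` are used.
    """
    _check_draw(scenario, draw)
    mu = float(draw.mu_l[0]) if mu is None else float(mu)
    p_geom = float(draw.p_l[0]) if p_geom is None else float(p_geom)
    pop_index = {lin.id: i for i, lin in enumerate(scenario.lineages)}
    sample_copies = np.array([2 * lin.sample_size for lin in scenario.lineages], np.int64)
    ne = np.array([draw.values[lin.ne_param] for lin in scenario.lineages], np.float64)
    if np.any(ne <= 0):
        raise ValueError("all effective sizes must be positive")
    ev = _encode_events(scenario, draw, pop_index)
    lo, hi = locus.window
    seed = int(rng.integers(0, 2**31 - 1))
    out, tmrca = _sim_locus_core(
        seed, sample_copies, ne, *ev, mu, p_geom, locus.ancestral_size, lo, hi
    )
    if out.size and out[0] == -1 and np.all(out == -1):
        raise RuntimeError(
            f"scenario {scenario.id}: genealogy did not coalesce to a single root "
            f"(disconnected populations after all events)"
        )
    if return_tmrca:
        return out, tmrca
    return out


def simulate_dataset(
    scenario: DemographicScenario,
    draw: ParameterDraw,
    loci: list[LocusSpec],
    rng: np.random.Generator,
    missing_rate: float = 0.0,
) -> GenotypeDataset:
    """Simulate a full diploid multi-locus dataset under one parameter draw.

    Loci are independent; consecutive gene copies within a population are
    paired into diploid individuals. ``missing_rate`` optionally masks each
    single-locus genotype (both alleles) independently with that
    probability. Deterministic for a given (scenario, draw, rng state).
    """
    _check_draw(scenario, draw)
    if len(draw.mu_l) < len(loci):
        raise ValueError("draw has fewer per-locus mutation rates than loci")
    pop_sizes = np.array([lin.sample_size for lin in scenario.lineages], np.int64)
    n_ind = int(pop_sizes.sum())
    n_loci = len(loci)
    genotypes = np.empty((n_ind, n_loci, 2), np.int16)
    # independent per-locus substream seeds drawn up-front from the dataset rng
    locus_seeds = rng.integers(0, 2**31 - 1, size=n_loci)
    pop_index = {lin.id: i for i, lin in enumerate(scenario.lineages)}
    sample_copies = 2 * pop_sizes
    ne = np.array([draw.values[lin.ne_param] for lin in scenario.lineages], np.float64)
    if np.any(ne <= 0):
        raise ValueError("all effective sizes must be positive")
    ev = _encode_events(scenario, draw, pop_index)
    for l, locus in enumerate(loci):
        lo, hi = locus.window
        copies, _ = _sim_locus_core(
            int(locus_seeds[l]),
            sample_copies,
            ne,
            *ev,
            float(draw.mu_l[l]),
            float(draw.p_l[l]),
            locus.ancestral_size,
            lo,
            hi,
        )
        if copies.size and copies[0] == -1 and np.all(copies == -1):
            raise RuntimeError(
                f"scenario {scenario.id}: genealogy did not coalesce to a single root"
            )
        genotypes[:, l, 0] = copies[0::2]
        genotypes[:, l, 1] = copies[1::2]
    if missing_rate > 0.0:
        mask = rng.random((n_ind, n_loci)) < missing_rate
        genotypes[mask] = MISSING
    return GenotypeDataset(
        populations=[lin.id for lin in scenario.lineages],
        pop_sizes=pop_sizes,
        loci=list(loci),
        genotypes=genotypes,
    )
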