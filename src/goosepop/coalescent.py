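"""Structured-coalescent simulation of two-population joint SFS.

Simulates genealogies of a sample from two demes (wild, domestic) under a
divergence model with piecewise-constant migration: backward in time the
recent epoch [0, T2) uses one migration matrix, the older epoch [T2, T1)
another, and at T1 all lineages merge into a panmictic ancestor of size
ANCSIZE. Time is in generations; sizes are diploid, so a pair of lineages
in a deme of size N coalesces at rate 1/(2N) per generation. Migration
follows the forward convention "M_XY is the per-generation fraction of deme
Y replaced by migrants from X": backward in time a lineage currently in Y
jumps to X at rate M_XY.

The expected SFS uses branch-length accumulation: under the infinite-sites
model the expected number of sites whose mutation subtends exactly (i, j)
sample copies is mu * E[L_ij] per site, where L_ij is the total branch
length carrying that leaf configuration. This is the exact expectation of
Poisson mutation dropping, with far lower Monte-Carlo variance. Because a
lineage's descendant configuration is fixed from its creation to its
coalescence, each lineage's branch contribution is credited once, at its
death, from its recorded birth time.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_SEED_MOD = 2**31 - 1


@njit(cache=True)
def _simulate_branch_lengths(
    seed: int,
    n_reps: int,
    n1: int,
    n2: int,
    anc_size: float,
    t1: float,
    n_wild: float,
    n_dom: float,
    t2: float,
    m1_wd: float,
    m1_dw: float,
    m2_wd: float,
    m2_dw: float,
) -> np.ndarray:
    """Mean branch length per (wild, domestic) descendant configuration."""
    np.random.seed(seed)
    k_total = n1 + n2
    acc = np.zeros((n1 + 1, n2 + 1))

    # lineages kept deme-partitioned: deme 0 occupies [0, k0), deme 1 [k0, k)
    cw = np.empty(k_total, np.int64)
    cd = np.empty(k_total, np.int64)
    born = np.empty(k_total, np.float64)

    for _ in range(n_reps):
        k = k_total
        k0 = n1
        for i in range(n1):
            cw[i] = 1
            cd[i] = 0
            born[i] = 0.0
        for i in range(n1, k_total):
            cw[i] = 0
            cd[i] = 1
            born[i] = 0.0
        t = 0.0
        merged = False
        while k > 1:
            if t >= t1 and not merged:
                k0 = k
                merged = True
            k1 = k - k0
            if not merged:
                if t < t2:
                    mw = m2_dw  # wild lineage's parent was a domestic migrant
                    md = m2_wd
                else:
                    mw = m1_dw
                    md = m1_wd
                rc0 = k0 * (k0 - 1) / 2.0 / (2.0 * n_wild)
                rc1 = k1 * (k1 - 1) / 2.0 / (2.0 * n_dom)
                rm0 = k0 * mw
                rm1 = k1 * md
                boundary = t2 if t < t2 else t1
            else:
                rc0 = k * (k - 1) / 2.0 / (2.0 * anc_size)
                rc1 = 0.0
                rm0 = 0.0
                rm1 = 0.0
                boundary = 1e300
            total = rc0 + rc1 + rm0 + rm1
            if total <= 0.0:
                t = boundary
                continue
            dt = np.random.exponential(1.0 / total)
            if t + dt >= boundary:
                t = boundary
                continue
            t += dt
            u = np.random.random() * total
            if u < rc0 + rc1:
                if u < rc0:
                    lo, kd = 0, k0
                else:
                    lo, kd = k0, k - k0
                a = lo + int(np.random.random() * kd)
                b = lo + int(np.random.random() * (kd - 1))
                if b >= a:
                    b += 1
                acc[cw[a], cd[a]] += t - born[a]
                acc[cw[b], cd[b]] += t - born[b]
                cw[a] += cw[b]
                cd[a] += cd[b]
                born[a] = t
                # delete b, preserving the partition
                if b < k0:
                    cw[b] = cw[k0 - 1]
                    cd[b] = cd[k0 - 1]
                    born[b] = born[k0 - 1]
                    cw[k0 - 1] = cw[k - 1]
                    cd[k0 - 1] = cd[k - 1]
                    born[k0 - 1] = born[k - 1]
                    k0 -= 1
                else:
                    cw[b] = cw[k - 1]
                    cd[b] = cd[k - 1]
                    born[b] = born[k - 1]
                k -= 1
            elif u < rc0 + rc1 + rm0:
                # a wild lineage's parent was in the domestic deme
                a = int(np.random.random() * k0)
                tw, td, tb = cw[a], cd[a], born[a]
                cw[a] = cw[k0 - 1]
                cd[a] = cd[k0 - 1]
                born[a] = born[k0 - 1]
                cw[k0 - 1] = tw
                cd[k0 - 1] = td
                born[k0 - 1] = tb
                k0 -= 1
            else:
                # a domestic lineage's parent was in the wild deme
                a = k0 + int(np.random.random() * (k - k0))
                tw, td, tb = cw[a], cd[a], born[a]
                cw[a] = cw[k0]
                cd[a] = cd[k0]
                born[a] = born[k0]
                cw[k0] = tw
                cd[k0] = td
                born[k0] = tb
                k0 += 1
    acc /= n_reps
    acc[0, 0] = 0.0
    return acc


def expected_branch_config_lengths(
    params,
    n_wild_chroms: int,
    n_dom_chroms: int,
    n_reps: int,
    seed: int,
) -> np.ndarray:
    """Monte-Carlo E[L_ij]: mean branch generations subtending each
    (wild, domestic) leaf configuration. Root configuration (n1, n2) is
    excluded (mutations there are invisible within the sample)."""
    if n_wild_chroms < 1 or n_dom_chroms < 1:
        raise ValueError("need at least one sampled chromosome per deme")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    acc = _simulate_branch_lengths(
        int(seed) % _SEED_MOD,
        int(n_reps),
        int(n_wild_chroms),
        int(n_dom_chroms),
        float(params.anc_size),
        float(params.t1),
        float(params.n_wild),
        float(params.n_dom),
        float(params.t2),
        float(params.m1_wd),
        float(params.m1_dw),
        float(params.m2_wd),
        float(params.m2_dw),
    )
    acc[n_wild_chroms, n_dom_chroms] = 0.0
    return acc
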