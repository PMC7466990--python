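"""PCA with Tracy–Widom axis significance, allele-sharing distances, and
neighbor-joining trees.

PCA follows the drift-scaled convention for SNP dosages: each locus is
centered by its mean dosage and divided by sqrt(p(1-p)) with p the sample
allele frequency, so every locus contributes variance proportional to its
drift information. Axis significance uses the Tracy–Widom (TW1) law for the
largest eigenvalue of a Wishart-like matrix, applied sequentially with the
effective-marker correction and stopping at the first non-significant axis.

The TW1 CDF is evaluated through Chiani's shifted-gamma approximation
(accurate to about 1e-4 over the relevant range), which keeps p-values
smooth without bundling a quantile table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from goosepop.genotype_io import MISSING, GenotypeMatrix

# Chiani (2014) gamma approximation to the beta=1 Tracy-Widom distribution:
# TW1 =~ Gamma(k, theta) - alpha
_TW1_K = 46.44604884387337
_TW1_THETA = 0.18605402228279682
_TW1_ALPHA = 9.848007781128567


def tracy_widom_sf(x: float | np.ndarray) -> np.ndarray:
    """P(TW1 > x) under the Tracy–Widom beta=1 law (gamma approximation)."""
    return stats.gamma.sf(np.asarray(x, dtype=float) + _TW1_ALPHA, _TW1_K, scale=_TW1_THETA)


def tracy_widom_ppf(q: float) -> float:
    """Quantile of the TW1 law (gamma approximation)."""
    return float(stats.gamma.ppf(q, _TW1_K, scale=_TW1_THETA) - _TW1_ALPHA)


@dataclass
class PcaResult:
    scores: np.ndarray  # individuals x retained axes
    eigenvalues: np.ndarray  # all non-trivial eigenvalues, non-increasing
    tw_statistics: np.ndarray  # per tested axis
    tw_p_values: np.ndarray  # per tested axis (testing stopped when ns)
    n_significant: int
    individuals: list[str]


def pca(gm: GenotypeMatrix, alpha: float = 0.05, n_axes: int | None = None) -> PcaResult:
    """Drift-scaled PCA of a genotype matrix with sequential TW1 tests.

    Missing dosages are mean-imputed per locus for the decomposition only.
    Monomorphic loci (no variance after imputation) are excluded.
    """
    if gm.n_individuals < 3:
        raise ValueError("PCA needs at least 3 individuals")
    dos = gm.dosages.astype(float)
    dos[gm.dosages == MISSING] = np.nan
    mu = np.nanmean(dos, axis=0)
    p_hat = mu / 2.0
    keep = (p_hat > 0) & (p_hat < 1) & np.isfinite(p_hat)
    if keep.sum() < 2:
        raise ValueError("PCA needs at least 2 polymorphic loci")
    x = dos[:, keep]
    mu = mu[keep]
    p_hat = p_hat[keep]
    inds = np.where(np.isnan(x))
    x[inds] = np.take(mu, inds[1])  # mean imputation
    x = (x - mu) / np.sqrt(p_hat * (1.0 - p_hat))

    m, n = x.shape
    cov = x @ x.T / n
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    # drop the trivial near-zero eigenvalue from centering
    evals_nt = evals[: m - 1]

    tw_stats: list[float] = []
    tw_p: list[float] = []
    n_sig = 0
    lam = evals_nt.copy()
    for k in range(len(lam)):
        rem = lam[k:]
        mprime = len(rem)
        if mprime < 2 or rem.sum() <= 0:
            break
        s1 = rem.sum()
        s2 = (rem**2).sum()
        denom = (mprime - 1) * s2 - s1**2
        # dispersion-based effective marker count; correlated loci reduce it.
        # On unlinked data the estimator overshoots, so cap at the true count
        n_eff = (mprime + 1) * s1**2 / denom if denom > 0 else n
        n_eff = min(n_eff, n)
        if n_eff <= 1:
            break
        ell = mprime * rem[0] / s1
        a, b = np.sqrt(n_eff - 1), np.sqrt(mprime)
        mu_tw = (a + b) ** 2 / n_eff
        sigma_tw = (a + b) / n_eff * (1.0 / a + 1.0 / b) ** (1.0 / 3.0)
        xstat = (ell - mu_tw) / sigma_tw
        pval = float(tracy_widom_sf(xstat))
        tw_stats.append(float(xstat))
        tw_p.append(pval)
        if pval < alpha:
            n_sig += 1
        else:
            break

    k_keep = n_axes if n_axes is not None else max(n_sig, 2)
    k_keep = min(k_keep, len(evals_nt))
    scores = evecs[:, :k_keep] * np.sqrt(np.maximum(evals[:k_keep], 0.0))
    return PcaResult(
        scores=scores,
        eigenvalues=evals_nt,
        tw_statistics=np.array(tw_stats),
        tw_p_values=np.array(tw_p),
        n_significant=n_sig,
        individuals=list(gm.individuals),
    )


# ---------------------------------------------------------------------------
# Distances and neighbor joining
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, zero diagonal
    n_shared_loci: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if (v < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.values = v


def pairwise_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """Allele-sharing distance: mean |dosage difference| over co-called loci,
    divided by the ploidy so values lie in [0, 1]."""
    m = gm.n_individuals
    dos = gm.dosages.astype(float)
    called = gm.dosages != MISSING
    values = np.zeros((m, m))
    shared = np.zeros((m, m), dtype=int)
    for i in range(m):
        for j in range(i + 1, m):
            both = called[i] & called[j]
            n_shared = int(both.sum())
            if n_shared == 0:
                raise ValueError(
                    f"individuals {gm.individuals[i]!r} and {gm.individuals[j]!r} "
                    "share no co-called locus"
                )
            d = np.abs(dos[i, both] - dos[j, both]).mean() / 2.0
            values[i, j] = values[j, i] = d
            shared[i, j] = shared[j, i] = n_shared
    return DistanceMatrix(list(gm.individuals), values, shared)


def write_phylip(dm: DistanceMatrix, path) -> None:
    """Write a PHYLIP square distance matrix (names truncated to 10 chars)."""
    with open(path, "wt") as fh:
        fh.write(f"{len(dm.labels)}\n")
        for label, row in zip(dm.labels, dm.values):
            fh.write(f"{label[:10]:<10}  " + "  ".join(f"{v:.6f}" for v in row) + "\n")


def nj_tree(dm: DistanceMatrix) -> str:
    """Neighbor-joining (Saitou–Nei) tree in Newick form.

    Deterministic: Q-criterion ties resolve to the lowest (i, j) index pair.
    Negative branch lengths are clamped to 0 with the deficit moved to the
    sister edge (their sum is preserved). The tree is unrooted; the Newick
    string has a trifurcating root.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.all(np.isfinite(dm.values)):
        bad = np.argwhere(~np.isfinite(dm.values))[0]
        raise ValueError(
            f"undefined distance between {dm.labels[bad[0]]!r} and {dm.labels[bad[1]]!r}"
        )
    d = dm.values.copy()
    newick = {i: dm.labels[i] for i in range(n)}
    active = list(range(n))
    next_id = n
    dist = {
        (i, j): d[i, j] for i in range(n) for j in range(n) if i < j
    }

    def get(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    def put(i: int, j: int, v: float) -> None:
        dist[(i, j) if i < j else (j, i)] = v

    while len(active) > 3:
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        m = len(active)
        best = None
        best_q = np.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * get(i, j) - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (i, j)
        i, j = best
        dij = get(i, j)
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        u = next_id
        next_id += 1
        newick[u] = f"({newick[i]}:{li:.10g},{newick[j]}:{lj:.10g})"
        for k in active:
            if k not in (i, j):
                put(u, k, 0.5 * (get(i, k) + get(j, k) - dij))
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = active
    la = 0.5 * (get(a, b) + get(a, c) - get(b, c))
    lb = 0.5 * (get(a, b) + get(b, c) - get(a, c))
    lc = 0.5 * (get(a, c) + get(b, c) - get(a, b))
    # clamp negatives, shifting the deficit to the longest sister edge
    lens = [la, lb, lc]
    for idx in range(3):
        if lens[idx] < 0:
            sister = int(np.argmax(lens))
            lens[sister] += lens[idx]
            lens[idx] = 0.0
    la, lb, lc = (max(v, 0.0) for v in lens)
    return f"({newick[a]}:{la:.10g},{newick[b]}:{lb:.10g},{newick[c]}:{lc:.10g});"
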