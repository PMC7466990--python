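"""Three-population admixture test f3(C; A, B) with block-jackknife errors.

The statistic estimates E[(c - a)(c - b)] over loci, where a, b, c are the
population allele frequencies of the two sources and the target. A
significantly negative value cannot be produced by tree-like ancestry and
signals that C is admixed between populations related to A and B. With
finite samples the naive product is biased upward by the sampling variance
of the target frequency, so the per-locus term subtracts its unbiased
estimate c(1-c)/(n_C - 1), with n_C the target's allele count (the
correction applies to the target only; no outgroup is needed: the noise in
a and b is uncorrelated with c and cancels in expectation). Standard
errors come from a
delete-one block jackknife over contiguous locus blocks and Z = f3/SE;
Z < -3 is the conventional admixture threshold (roughly P < 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from goosepop.genotype_io import GenotypeMatrix, PopulationMap, allele_frequency


@dataclass(frozen=True)
class F3Result:
    f3: float
    se: float
    z: float
    n_blocks: int
    n_loci_used: int


def _block_jackknife(terms: np.ndarray, block_size: int) -> tuple[float, float, int]:
    """Weighted delete-one block jackknife mean and SE over contiguous blocks."""
    n = len(terms)
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    starts = np.arange(0, n, block_size)
    g = len(starts)
    if g < 2:
        raise ValueError(
            f"need >= 2 jackknife blocks, got {g} (n_loci={n}, block_size={block_size})"
        )
    total = terms.sum()
    theta = total / n
    sizes = np.minimum(starts + block_size, n) - starts
    block_sums = np.add.reduceat(terms, starts)
    theta_minus = (total - block_sums) / (n - sizes)
    # Busing-style weighted jackknife; reduces to the textbook formula for
    # equal block sizes.
    h = n / sizes
    theta_j = g * theta - ((1 - sizes / n) * theta_minus).sum()
    tau = h * theta - (h - 1) * theta_minus
    var = float(np.sum((tau - theta_j) ** 2 / (h - 1)) / g)
    return float(theta), float(np.sqrt(var)), g


def f3_from_frequencies(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    n_c: np.ndarray | None = None,
    block_size: int = 500,
) -> F3Result:
    """f3 from population allele frequencies directly.

    Without ``n_c`` the frequencies are treated as exactly known and no
    finite-sample correction is applied (hand-checkable oracle mode). With
    ``n_c`` (target allele counts per locus) the unbiased correction
    h_C/n_C is subtracted per locus.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    terms = (c - a) * (c - b)
    if n_c is not None:
        # E[(c_hat - a)(c_hat - b)] = (c-a)(c-b) + Var(c_hat); the unbiased
        # estimate of Var(c_hat) = c(1-c)/n is c_hat(1-c_hat)/(n-1)
        n_c = np.asarray(n_c, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = terms - c * (1 - c) / np.maximum(n_c - 1, 1)
    f3, se, g = _block_jackknife(terms, block_size)
    z = f3 / se if se > 0 else float("nan")
    return F3Result(f3=f3, se=se, z=z, n_blocks=g, n_loci_used=len(terms))


def f3_test(
    gm: GenotypeMatrix,
    target: str,
    source_a: str,
    source_b: str,
    popmap: PopulationMap,
    block_size: int = 500,
) -> F3Result:
    """f3(target; source_a, source_b) from genotypes.

    Loci with no called genotype in any of the three populations, or
    monomorphic across all three, are dropped before blocking (they carry
    no signal and would distort block counts). Blocks are contiguous runs
    of ``block_size`` loci in genome order.
    """
    if len({target, source_a, source_b}) != 3:
        raise ValueError("target and sources must be three distinct populations")
    for pop in (target, source_a, source_b):
        idx = popmap.indices(gm, pop)
        if len(idx) < 2:
            raise ValueError(f"population {pop!r} needs >= 2 genotyped individuals")
    fa, _ = allele_frequency(gm, source_a, popmap)
    fb, _ = allele_frequency(gm, source_b, popmap)
    fc, nc = allele_frequency(gm, target, popmap)
    defined = np.isfinite(fa) & np.isfinite(fb) & np.isfinite(fc) & (nc > 1)
    poly = ~((fa == fb) & (fb == fc) & ((fc == 0) | (fc == 1)))
    use = defined & poly
    if use.sum() == 0:
        raise ValueError("no usable loci for the f3 test")
    return f3_from_frequencies(
        fa[use], fb[use], fc[use], n_c=nc[use].astype(float), block_size=block_size
    )
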