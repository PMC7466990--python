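"""Per-population expected heterozygosity and the Welch group comparison.

Expected heterozygosity (gene diversity) is computed per locus and
population with the small-sample correction

    H_E = 2n/(2n - 1) * (1 - p^2 - q^2)

where ``n`` is the number of non-missing diploids and ``p`` the alternate
allele frequency; the naive ``2pq`` form is available for oracle
comparisons. Per-population means are taken across loci with a defined
value; loci monomorphic in a population contribute H_E = 0 rather than
being dropped. The wild-vs-domestic comparison is a two-sided Welch t-test
on the per-population means (the population, not the locus, is the sampling
unit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from goosepop.genotype_io import GenotypeMatrix, PopulationMap, allele_frequency


@dataclass
class HeterozygosityTable:
    populations: list[str]
    per_locus: np.ndarray  # shape (n_loci, n_populations); nan where undefined
    mean_he: dict[str, float]
    n_defined_loci: dict[str, int]


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p_value: float
    mean_x: float
    mean_y: float


def expected_heterozygosity(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    populations: list[str] | None = None,
    unbiased: bool = True,
) -> HeterozygosityTable:
    """Unbiased gene diversity per (locus, population) cell and its mean.

    Cells with no non-missing genotype are undefined (nan) and excluded from
    the mean; ``unbiased=False`` switches to the naive 2pq estimator.
    """
    popmap.validate_against(gm)
    pops = populations if populations is not None else popmap.populations
    table = np.full((gm.n_loci, len(pops)), np.nan)
    mean_he: dict[str, float] = {}
    n_def: dict[str, int] = {}
    for k, pop in enumerate(pops):
        freq, counts = allele_frequency(gm, pop, popmap)
        n = counts / 2  # non-missing diploids per locus
        defined = counts > 0
        p = freq[defined]
        nn = n[defined]
        h = 1.0 - p**2 - (1.0 - p) ** 2
        if unbiased:
            h = np.where(2 * nn > 1, (2 * nn / (2 * nn - 1)) * h, h)
        col = np.full(gm.n_loci, np.nan)
        col[defined] = h
        table[:, k] = col
        mean_he[pop] = float(np.nanmean(col)) if defined.any() else float("nan")
        n_def[pop] = int(defined.sum())
    return HeterozygosityTable(list(pops), table, mean_he, n_def)


def welch_t_test(x: np.ndarray, y: np.ndarray) -> WelchResult:
    """Two-sided Welch t-test (unequal variances) on two samples of means."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValueError("degenerate variance: both samples are constant")
    res = stats.ttest_ind(x, y, equal_var=False)
    return WelchResult(
        t=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        mean_x=float(x.mean()),
        mean_y=float(y.mean()),
    )
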