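"""Pairwise Weir–Cockerham F_ST and locus-by-locus hierarchical AMOVA.

F_ST uses the Weir & Cockerham (1984) variance-component estimator with
multi-locus combining as a ratio of sums (sum a / sum (a+b+c)), the standard
choice for genome-wide SNP data. The AMOVA partitions allele-copy variance
into three strata (among groups, among populations within groups, within
populations) with unequal-size coefficients, summing per-locus components
in locus-by-locus mode, and tests each fixation index with its own
permutation scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from goosepop.genotype_io import MISSING, GenotypeMatrix, PopulationMap


@dataclass
class FstMatrix:
    populations: list[str]
    values: np.ndarray  # symmetric, nan where undefined
    n_loci_used: np.ndarray  # per-pair count of loci entering the estimate

    def pair(self, a: str, b: str) -> float:
        i, j = self.populations.index(a), self.populations.index(b)
        return float(self.values[i, j])

    def mean_between_groups(self, popmap: PopulationMap, group_a: str, group_b: str) -> float:
        """Mean pairwise F_ST over (group_a population, group_b population) pairs."""
        vals = []
        for i, p in enumerate(self.populations):
            for j, q in enumerate(self.populations):
                if i < j:
                    gp, gq = popmap.group_of(p), popmap.group_of(q)
                    if {gp, gq} == {group_a, group_b} or (
                        group_a == group_b and gp == gq == group_a and p != q
                    ):
                        if np.isfinite(self.values[i, j]):
                            vals.append(self.values[i, j])
        return float(np.mean(vals)) if vals else float("nan")


def _wc84_components(
    dos_by_pop: list[np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus WC84 a, b, c for r populations given dosage sub-matrices.

    Returns (a, b, c, usable) arrays over loci; ``usable`` marks loci where
    every population has >= 1 called diploid and the locus is polymorphic
    across the pooled sample (monomorphic loci contribute nothing to either
    numerator or denominator and are skipped, as is conventional).
    """
    r = len(dos_by_pop)
    n_loci = dos_by_pop[0].shape[1]
    n = np.zeros((r, n_loci))
    p = np.zeros((r, n_loci))
    h = np.zeros((r, n_loci))
    for k, dos in enumerate(dos_by_pop):
        called = dos != MISSING
        nk = called.sum(axis=0)
        alt = np.where(called, np.maximum(dos, 0), 0).sum(axis=0)
        het = ((dos == 1) & called).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p[k] = np.where(nk > 0, alt / np.maximum(2 * nk, 1), np.nan)
            h[k] = np.where(nk > 0, het / np.maximum(nk, 1), np.nan)
        n[k] = nk
    usable = (n > 0).all(axis=0)
    # WC84 needs n_bar > 1 for the (n_bar - 1) denominators
    n_bar = n.mean(axis=0)
    usable &= n_bar > 1
    n_total = n.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        n_c = (n_total - (n**2).sum(axis=0) / np.maximum(n_total, 1)) / (r - 1)
        p_bar = (n * p).sum(axis=0) / np.maximum(n_total, 1)
        s2 = (n * (p - p_bar) ** 2).sum(axis=0) / np.maximum((r - 1) * n_bar, 1e-300)
        h_bar = (n * h).sum(axis=0) / np.maximum(n_total, 1)
        pq = p_bar * (1 - p_bar)
        a = (n_bar / np.maximum(n_c, 1e-300)) * (
            s2
            - (pq - (r - 1) / r * s2 - h_bar / 4) / np.maximum(n_bar - 1, 1e-300)
        )
        b = (n_bar / np.maximum(n_bar - 1, 1e-300)) * (
            pq - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
        )
        c = h_bar / 2
    poly = usable & (p_bar > 0) & (p_bar < 1)
    return a, b, c, poly


def wc84_fst(dos_by_pop: list[np.ndarray]) -> tuple[float, int]:
    """Multi-locus WC84 theta for r populations (ratio of sums), and the
    number of loci used."""
    a, b, c, usable = _wc84_components(dos_by_pop)
    num = a[usable].sum()
    den = (a + b + c)[usable].sum()
    if usable.sum() == 0 or den == 0:
        return float("nan"), int(usable.sum())
    return float(num / den), int(usable.sum())


def pairwise_fst(gm: GenotypeMatrix, popmap: PopulationMap) -> FstMatrix:
    """Pairwise WC84 F_ST between all populations in the map."""
    popmap.validate_against(gm)
    pops = popmap.populations
    if len(pops) < 2:
        raise ValueError("pairwise F_ST needs at least two populations")
    sub = {p: gm.dosages[popmap.indices(gm, p)] for p in pops}
    k = len(pops)
    values = np.zeros((k, k))
    used = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            fst, n_used = wc84_fst([sub[pops[i]], sub[pops[j]]])
            values[i, j] = values[j, i] = fst
            used[i, j] = used[j, i] = n_used
    return FstMatrix(pops, values, used)


# ---------------------------------------------------------------------------
# Hierarchical AMOVA
# ---------------------------------------------------------------------------


@dataclass
class AmovaResult:
    ss_among_groups: float
    ss_among_pops: float
    ss_within_pops: float
    sigma2_a: float  # among groups
    sigma2_b: float  # among populations within groups
    sigma2_c: float  # within populations
    pct_among_groups: float
    pct_among_pops: float
    pct_within_pops: float
    f_ct: float
    f_sc: float
    f_st: float
    p_f_ct: float | None
    p_f_sc: float | None
    p_f_st: float | None
    n_permutations: int

    @property
    def sigma2_total(self) -> float:
        return self.sigma2_a + self.sigma2_b + self.sigma2_c

    def to_dict(self) -> dict:
        return {
            "among_groups": {
                "sum_of_squares": self.ss_among_groups,
                "variance_component": self.sigma2_a,
                "percentage_variation": self.pct_among_groups,
                "fixation_index_FCT": self.f_ct,
                "p_value": self.p_f_ct,
            },
            "among_populations_within_groups": {
                "sum_of_squares": self.ss_among_pops,
                "variance_component": self.sigma2_b,
                "percentage_variation": self.pct_among_pops,
                "fixation_index_FSC": self.f_sc,
                "p_value": self.p_f_sc,
            },
            "within_populations": {
                "sum_of_squares": self.ss_within_pops,
                "variance_component": self.sigma2_c,
                "percentage_variation": self.pct_within_pops,
                "fixation_index_FST": self.f_st,
                "p_value": self.p_f_st,
            },
            "n_permutations": self.n_permutations,
        }


def _amova_components(
    dosages: np.ndarray,
    called: np.ndarray,
    pop_of_ind: np.ndarray,
    group_of_pop: np.ndarray,
    n_pops: int,
    n_groups: int,
) -> tuple[float, float, float, float, float, float]:
    """Summed per-locus SSD and variance components for a 3-level hierarchy.

    Units are allele copies (each called diploid contributes two binary
    copies, so per-set sums of squares reduce to dosage sums). Returns
    (SS_a, SS_b, SS_c, sigma2_a, sigma2_b, sigma2_c).
    """
    n_loci = dosages.shape[1]
    dos = np.where(called, np.maximum(dosages, 0), 0).astype(float)

    # population x locus allele-copy counts and alt sums
    pop_ind = np.zeros((n_pops, dosages.shape[0]))
    pop_ind[pop_of_ind, np.arange(dosages.shape[0])] = 1.0
    n_p = 2.0 * (pop_ind @ called)  # copies per pop per locus
    s_p = pop_ind @ dos  # alt copies per pop per locus

    grp_ind = np.zeros((n_groups, n_pops))
    grp_ind[group_of_pop, np.arange(n_pops)] = 1.0
    n_g = grp_ind @ n_p
    s_g = grp_ind @ s_p
    n_t = n_p.sum(axis=0)
    s_t = s_p.sum(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        # binary copies: sum of squared copies == sum of copies
        ss_total = s_t - s_t**2 / np.maximum(n_t, 1)
        ss_within_pop = (s_p - s_p**2 / np.maximum(n_p, 1)).sum(axis=0)
        ss_within_grp = (s_g - s_g**2 / np.maximum(n_g, 1)).sum(axis=0)
    ss_c = ss_within_pop
    ss_b = ss_within_grp - ss_within_pop
    ss_a = ss_total - ss_within_grp

    df_a = n_groups - 1
    # per-locus dfs depend on which pops/groups have copies at that locus
    pops_present = (n_p > 0).sum(axis=0)
    groups_present = (n_g > 0).sum(axis=0)
    df_a_l = np.maximum(groups_present - 1, 0)
    df_b_l = np.maximum(pops_present - groups_present, 0)
    df_c_l = np.maximum(n_t - pops_present, 0)

    # unequal-size coefficients, per locus
    with np.errstate(divide="ignore", invalid="ignore"):
        sum_np2_over_ng = (
            grp_ind @ (n_p**2) / np.maximum(n_g, 1)
        ).sum(axis=0)
        sum_np2_over_nt = (n_p**2).sum(axis=0) / np.maximum(n_t, 1)
        sum_ng2_over_nt = (n_g**2).sum(axis=0) / np.maximum(n_t, 1)
        n1 = (n_t - sum_np2_over_ng) / np.maximum(df_b_l, 1)
        n2 = (sum_np2_over_ng - sum_np2_over_nt) / np.maximum(df_a_l, 1)
        n3 = (n_t - sum_ng2_over_nt) / np.maximum(df_a_l, 1)

        ms_a = ss_a / np.maximum(df_a_l, 1)
        ms_b = ss_b / np.maximum(df_b_l, 1)
        ms_c = ss_c / np.maximum(df_c_l, 1)

        sig_c = ms_c
        sig_b = (ms_b - sig_c) / np.maximum(n1, 1e-300)
        sig_a = (ms_a - sig_c - n2 * sig_b) / np.maximum(n3, 1e-300)

    # loci contribute to each stratum only where its df and coefficient are
    # defined (a single group still yields within/among-population terms)
    ok_bc = (df_c_l > 0) & (df_b_l > 0) & (n1 > 0)
    ok_a = ok_bc & (df_a_l > 0) & (n3 > 0)
    del df_a, n_loci
    return (
        float(ss_a[ok_a].sum()),
        float(ss_b[ok_bc].sum()),
        float(ss_c[ok_bc].sum()),
        float(sig_a[ok_a].sum()),
        float(sig_b[ok_bc].sum()),
        float(sig_c[ok_bc].sum()),
    )


def _indices_from(sig_a: float, sig_b: float, sig_c: float) -> tuple[float, float, float]:
    total = sig_a + sig_b + sig_c
    f_ct = sig_a / total if total != 0 else float("nan")
    f_sc = sig_b / (sig_b + sig_c) if (sig_b + sig_c) != 0 else float("nan")
    f_st = (sig_a + sig_b) / total if total != 0 else float("nan")
    return f_ct, f_sc, f_st


def amova(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    n_perm: int = 16000,
    seed: int = 0,
) -> AmovaResult:
    """Locus-by-locus hierarchical AMOVA with permutation tests.

    Permutation schemes: whole populations among groups (F_CT),
    individuals among populations within groups (F_SC), individuals among
    all populations (F_ST); p = (#{perm >= observed} + 1)/(n_perm + 1).
    A single group leaves F_CT undefined (p-values None).
    """
    popmap.validate_against(gm)
    pops = popmap.populations
    groups = sorted({popmap.group_of(p) for p in pops})
    if len(pops) < 2:
        raise ValueError("AMOVA needs at least two populations")
    pop_idx = {p: i for i, p in enumerate(pops)}
    grp_idx = {g: i for i, g in enumerate(groups)}
    pop_of_ind = np.array(
        [pop_idx[popmap.individual_to_population[i]] for i in gm.individuals]
    )
    group_of_pop = np.array([grp_idx[popmap.group_of(p)] for p in pops])

    called = gm.dosages != MISSING

    ss_a, ss_b, ss_c, sig_a, sig_b, sig_c = _amova_components(
        gm.dosages, called, pop_of_ind, group_of_pop, len(pops), len(groups)
    )
    f_ct, f_sc, f_st = _indices_from(sig_a, sig_b, sig_c)
    total = sig_a + sig_b + sig_c

    rng = np.random.default_rng(seed)
    p_ct = p_sc = p_st = None
    if n_perm > 0 and len(groups) > 1:
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(group_of_pop)
            *_, sa, sb, sc = _amova_components(
                gm.dosages, called, pop_of_ind, perm, len(pops), len(groups)
            )
            if _indices_from(sa, sb, sc)[0] >= f_ct:
                hits += 1
        p_ct = (hits + 1) / (n_perm + 1)
    if n_perm > 0:
        # F_SC: shuffle individuals among populations within their group
        grp_of_ind = group_of_pop[pop_of_ind]
        hits = 0
        for _ in range(n_perm):
            perm = pop_of_ind.copy()
            for g in range(len(groups)):
                sel = np.flatnonzero(grp_of_ind == g)
                perm[sel] = perm[rng.permutation(sel)]
            *_, sa, sb, sc = _amova_components(
                gm.dosages, called, perm, group_of_pop, len(pops), len(groups)
            )
            if _indices_from(sa, sb, sc)[1] >= f_sc:
                hits += 1
        p_sc = (hits + 1) / (n_perm + 1)
        # F_ST: shuffle individuals among all populations
        hits = 0
        for _ in range(n_perm):
            perm = pop_of_ind[rng.permutation(len(pop_of_ind))]
            *_, sa, sb, sc = _amova_components(
                gm.dosages, called, perm, group_of_pop, len(pops), len(groups)
            )
            if _indices_from(sa, sb, sc)[2] >= f_st:
                hits += 1
        p_st = (hits + 1) / (n_perm + 1)

    pct = (
        (100 * sig_a / total, 100 * sig_b / total, 100 * sig_c / total)
        if total != 0
        else (float("nan"),) * 3
    )
    return AmovaResult(
        ss_among_groups=ss_a,
        ss_among_pops=ss_b,
        ss_within_pops=ss_c,
        sigma2_a=sig_a,
        sigma2_b=sig_b,
        sigma2_c=sig_c,
        pct_among_groups=pct[0],
        pct_among_pops=pct[1],
        pct_within_pops=pct[2],
        f_ct=f_ct if len(groups) > 1 else float("nan"),
        f_sc=f_sc,
        f_st=f_st,
        p_f_ct=p_ct,
        p_f_sc=p_sc,
        p_f_st=p_st,
        n_permutations=n_perm,
    )
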