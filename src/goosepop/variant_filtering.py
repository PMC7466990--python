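"""Post-calling variant and individual filters, and SFS site accounting.

The filters reproduce a GBS study's post-pipeline cleanup: drop indels,
multi-allelic loci and within-dataset-invariant loci, remove putative
paralogs (observed heterozygosity strictly above 0.75), and drop individuals
with more than 20% missing genotypes. Each removed locus is attributed to
exactly one rule, applied in a fixed order (indel -> multi-allelic ->
invariant -> heterozygosity) so per-rule counts are deterministic.

Site accounting turns a count of callable base pairs into the monomorphic
class of an SFS: sites removed by absolute-count filters (indel,
multi-allelic, heterozygosity) are subtracted outright, then the total is
scaled down by the same proportion of SNPs lost to missing-data
completeness, and the kept SNPs are the polymorphic class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from goosepop.genotype_io import MISSING, GenotypeMatrix

RULES = ("indel", "multi_allelic", "invariant", "heterozygosity_excess")


@dataclass
class FilterReport:
    """Per-rule removal counts plus input/output dimensions."""

    input_loci: int
    output_loci: int
    input_individuals: int
    output_individuals: int
    removed: dict[str, int] = field(default_factory=dict)
    removed_individuals: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        total_removed = sum(self.removed.values())
        if self.input_loci - total_removed != self.output_loci:
            raise ValueError(
                "inconsistent report: input_loci - removed != output_loci "
                f"({self.input_loci} - {total_removed} != {self.output_loci})"
            )

    def to_dict(self) -> dict:
        return {
            "input_loci": self.input_loci,
            "output_loci": self.output_loci,
            "input_individuals": self.input_individuals,
            "output_individuals": self.output_individuals,
            "removed": dict(self.removed),
            "removed_individuals": list(self.removed_individuals),
        }


@dataclass(frozen=True)
class SiteAccounts:
    """Callable-site bookkeeping behind an SFS monomorphic class."""

    total_sites: int
    monomorphic: int
    polymorphic: int

    def __post_init__(self) -> None:
        if self.monomorphic + self.polymorphic != self.total_sites:
            raise ValueError("monomorphic + polymorphic must equal total_sites")


def observed_heterozygosity(gm: GenotypeMatrix) -> np.ndarray:
    """Per-locus fraction of heterozygotes among non-missing genotypes."""
    called = gm.dosages != MISSING
    het = gm.dosages == 1
    n_called = called.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ho = np.where(n_called > 0, het.sum(axis=0) / np.maximum(n_called, 1), np.nan)
    return ho


def apply_site_filters(
    gm: GenotypeMatrix,
    max_het: float = 0.75,
    keep_cross_species_divergent: bool = False,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop indel, multi-allelic, invariant and heterozygosity-excess loci.

    ``keep_cross_species_divergent`` retains loci invariant within the
    dataset but fixed for a non-reference allele (useful when the mapping
    reference is a related species and cross-species divergence is wanted,
    e.g. for phylogenetics).
    """
    n_loci = gm.n_loci
    keep = np.ones(n_loci, dtype=bool)
    removed = {rule: 0 for rule in RULES}

    is_indel = np.array([loc.is_indel for loc in gm.loci])
    is_multi = np.array([not loc.is_biallelic for loc in gm.loci], dtype=bool)

    called = gm.dosages != MISSING
    alt_sum = np.where(called, np.maximum(gm.dosages, 0), 0).sum(axis=0)
    n_called = called.sum(axis=0)
    # invariant within dataset: all non-missing calls carry the same genotype class
    all_ref = alt_sum == 0
    all_alt_hom = (alt_sum == 2 * n_called) & (n_called > 0)
    invariant = all_ref | all_alt_hom
    if keep_cross_species_divergent:
        invariant = invariant & ~all_alt_hom  # fixed-nonreference loci survive

    ho = observed_heterozygosity(gm)
    het_excess = np.nan_to_num(ho, nan=0.0) > max_het

    for rule, mask in (
        ("indel", is_indel),
        ("multi_allelic", is_multi),
        ("invariant", invariant),
        ("heterozygosity_excess", het_excess),
    ):
        hits = mask & keep
        removed[rule] = int(hits.sum())
        keep &= ~hits

    out = gm.subset_loci(keep)
    report = FilterReport(
        input_loci=n_loci,
        output_loci=out.n_loci,
        input_individuals=gm.n_individuals,
        output_individuals=gm.n_individuals,
        removed=removed,
    )
    return out, report


def apply_individual_filter(
    gm: GenotypeMatrix, max_missing: float = 0.20
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop individuals whose missing fraction strictly exceeds ``max_missing``."""
    if not 0.0 <= max_missing <= 1.0:
        raise ValueError("max_missing must be in [0, 1]")
    frac = gm.individual_missing_fraction()
    keep = frac <= max_missing
    out = gm.subset_individuals(keep)
    report = FilterReport(
        input_loci=gm.n_loci,
        output_loci=gm.n_loci,
        input_individuals=gm.n_individuals,
        output_individuals=out.n_individuals,
        removed={},
        removed_individuals=[
            ind for ind, k in zip(gm.individuals, keep) if not k
        ],
    )
    return out, report


def site_accounting(
    covered_bp: int,
    absolute_removed: int,
    proportional_kept_fraction: float,
    kept_snps: int,
) -> SiteAccounts:
    """Derive SFS site totals by mimicking the SNP filters on callable sites.

    Parameters
    ----------
    covered_bp
        Callable base pairs covered by sequencing tags.
    absolute_removed
        Sites removed outright (indel + multi-allelic + heterozygosity-excess
        SNP counts; these filters act on absolute site identity).
    proportional_kept_fraction
        Fraction of SNPs surviving the missing-data completeness filter; the
        same proportion of callable sites is retained.
    kept_snps
        SNPs entering the SFS (the polymorphic class).
    """
    if covered_bp < 0 or absolute_removed < 0 or kept_snps < 0:
        raise ValueError("negative counts in site accounting")
    if not 0.0 < proportional_kept_fraction <= 1.0:
        raise ValueError("proportional_kept_fraction must be in (0, 1]")
    after_absolute = covered_bp - absolute_removed
    if after_absolute < 0:
        raise ValueError("absolute removals exceed covered sites")
    total = int(round(after_absolute * proportional_kept_fraction))
    mono = total - kept_snps
    if mono < 0:
        raise ValueError("kept SNPs exceed accounted total sites")
    return SiteAccounts(total_sites=total, monomorphic=mono, polymorphic=kept_snps)


def site_accounting_from_report(
    report: FilterReport, covered_bp: int, kept_snps: int
) -> SiteAccounts:
    """Site accounting driven by a site-filter :class:`FilterReport`.

    Indel, multi-allelic and heterozygosity-excess removals subtract sites
    outright. Invariant loci are not subtracted: they remain callable
    monomorphic sites. SNPs later dropped for missing-data completeness
    (``report.output_loci`` biallelic SNPs down to ``kept_snps``) remove the
    same *proportion* of callable sites.
    """
    if covered_bp < report.input_loci:
        raise ValueError("covered_bp smaller than the number of input loci")
    absolute = (
        report.removed.get("indel", 0)
        + report.removed.get("multi_allelic", 0)
        + report.removed.get("heterozygosity_excess", 0)
    )
    if report.output_loci <= 0:
        raise ValueError("no SNPs survived the site filters")
    kept_fraction = kept_snps / report.output_loci
    return site_accounting(covered_bp, absolute, kept_fraction, kept_snps)
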