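"""Genotype matrices, population maps, and VCF interchange.

The in-memory container is a diploid allele-dosage matrix (individuals x
loci, values 0/1/2 or MISSING) with per-locus metadata preserved from the
VCF. Phase is ignored ("0/1" and "0|1" are the same dosage) and half-calls
("./1") are treated as missing. Positions stay 1-based as in VCF.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

try:  # cyvcf2 backs the reader; import deferred errors surface at call time
    from cyvcf2 import VCF as _CyVCF
except ImportError:  # pragma: no cover
    _CyVCF = None

#: Sentinel for a missing diploid genotype in the dosage matrix.
MISSING: int = -1

_SNP_ALPHABET = frozenset("ACGT")

WILD = "wild"
DOMESTIC_EUROPEAN = "domestic_european"
DOMESTIC_CHINESE = "domestic_chinese"
GROUPS = (WILD, DOMESTIC_EUROPEAN, DOMESTIC_CHINESE)


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed; carries a line number when known."""


@dataclass(frozen=True)
class LocusRecord:
    """One variant site: chromosome, 1-based position, ref and alt alleles."""

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]

    @property
    def is_indel(self) -> bool:
        if len(self.ref) != 1 or not set(self.ref) <= _SNP_ALPHABET:
            return True
        for alt in self.alts:
            if len(alt) != 1 or not set(alt) <= _SNP_ALPHABET:
                return True
        return False

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix: ``dosages[i, j]`` counts ALT alleles of
    individual ``i`` at locus ``j`` (0, 1, 2) or :data:`MISSING`."""

    individuals: list[str]
    loci: list[LocusRecord]
    dosages: np.ndarray  # int8, shape (n_individuals, n_loci)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.individuals), len(self.loci)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or MISSING")
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicate individual identifiers")
        keys = {(l.chrom, l.pos) for l in self.loci}
        if len(keys) != len(self.loci):
            raise ValueError("duplicate (chromosome, position) loci")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def individual_missing_fraction(self) -> np.ndarray:
        if self.n_loci == 0:
            return np.zeros(self.n_individuals)
        return self.missing_mask().mean(axis=1)

    def subset_individuals(self, keep: list[str] | np.ndarray) -> "GenotypeMatrix":
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {name: i for i, name in enumerate(self.individuals)}
            idx = np.array([pos[name] for name in keep], dtype=int)
        return GenotypeMatrix(
            [self.individuals[i] for i in idx], list(self.loci), self.dosages[idx]
        )

    def subset_loci(self, keep: np.ndarray) -> "GenotypeMatrix":
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = np.asarray(keep, dtype=int)
        return GenotypeMatrix(
            list(self.individuals), [self.loci[j] for j in idx], self.dosages[:, idx]
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.loci == other.loci
            and np.array_equal(self.dosages, other.dosages)
        )


@dataclass
class PopulationMap:
    """individual -> population -> group assignment.

    Groups partition populations: every population belongs to exactly one of
    ``wild``, ``domestic_european``, ``domestic_chinese``. An optional purity
    flag marks populations with < 10% admixture from the other gene pool.
    """

    individual_to_population: dict[str, str]
    population_to_group: dict[str, str]
    purity: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pop, grp in self.population_to_group.items():
            if grp not in GROUPS:
                raise ValueError(f"unknown group {grp!r} for population {pop!r}")
        for ind, pop in self.individual_to_population.items():
            if pop not in self.population_to_group:
                raise ValueError(f"individual {ind!r} assigned to unmapped population {pop!r}")

    @property
    def populations(self) -> list[str]:
        return sorted(self.population_to_group)

    def members(self, population: str) -> list[str]:
        if population not in self.population_to_group:
            raise KeyError(f"unknown population {population!r}")
        return [i for i, p in self.individual_to_population.items() if p == population]

    def group_of(self, population: str) -> str:
        return self.population_to_group[population]

    def populations_in_group(self, group: str) -> list[str]:
        return sorted(p for p, g in self.population_to_group.items() if g == group)

    def indices(self, gm: GenotypeMatrix, population: str) -> np.ndarray:
        """Row indices of a population's genotyped members in ``gm``."""
        names = set(self.members(population))
        return np.array(
            [i for i, ind in enumerate(gm.individuals) if ind in names], dtype=int
        )

    def validate_against(self, gm: GenotypeMatrix) -> None:
        unassigned = [i for i in gm.individuals if i not in self.individual_to_population]
        if unassigned:
            raise ValueError(f"individuals without population assignment: {unassigned[:5]}")


def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Read a VCF (GT fields) into a :class:`GenotypeMatrix`.

    ``./.`` and half-calls become :data:`MISSING`; multi-allelic records are
    retained with all alts listed (dosage counts any non-reference allele);
    filtering is a downstream concern.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    _prescan_header(path)
    if _CyVCF is None:  # pragma: no cover
        raise ImportError("cyvcf2 is required to read VCF files")
    try:
        vcf = _CyVCF(path)
    except Exception as exc:  # htslib-level failure
        raise VcfParseError(f"cannot parse VCF {path!r}: {exc}") from exc
    individuals = list(vcf.samples)
    loci: list[LocusRecord] = []
    rows: list[np.ndarray] = []
    try:
        for rec in vcf:
            loci.append(
                LocusRecord(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alts=tuple(rec.ALT),
                )
            )
            # gt_types collapses het phases; derive dosage from genotype tuples
            # so multi-allelic alts all count toward the alternate dosage.
            col = np.empty(len(individuals), dtype=np.int8)
            for i, gt in enumerate(rec.genotypes):
                a, b = gt[0], gt[1]
                if a < 0 or b < 0:  # missing or half-call
                    col[i] = MISSING
                else:
                    col[i] = (a > 0) + (b > 0)
            rows.append(col)
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(
            f"malformed record near locus {len(loci)} in {path!r}: {exc}"
        ) from exc
    dosages = (
        np.stack(rows, axis=1) if rows else np.empty((len(individuals), 0), dtype=np.int8)
    )
    return GenotypeMatrix(individuals, loci, dosages)


def _prescan_header(path: str) -> None:
    """Cheap header sanity check that can name the offending line number."""
    with open(path, "rt") as fh:
        first = fh.readline()
        if not first.startswith("##fileformat=VCF"):
            raise VcfParseError(f"{path!r} line 1: missing ##fileformat=VCF header")
        for lineno, line in enumerate(fh, start=2):
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                n_fields = len(line.rstrip("\n").split("\t"))
                if n_fields < 8:
                    raise VcfParseError(
                        f"{path!r} line {lineno}: truncated #CHROM header line"
                    )
                return
            raise VcfParseError(
                f"{path!r} line {lineno}: expected ## meta line or #CHROM header"
            )
    raise VcfParseError(f"{path!r}: no #CHROM header line found")


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a minimal VCF 4.2 with a GT-only FORMAT column."""
    path = os.fspath(path)
    with open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        contigs = []
        for loc in gm.loci:
            if loc.chrom not in contigs:
                contigs.append(loc.chrom)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(cols + gm.individuals) + "\n")
        for j, loc in enumerate(gm.loci):
            gts = [_GT_STRINGS[int(d)] for d in gm.dosages[:, j]]
            fields = [
                loc.chrom,
                str(loc.pos),
                ".",
                loc.ref,
                ",".join(loc.alts),
                ".",
                "PASS",
                ".",
                "GT",
            ]
            fh.write("\t".join(fields + gts) + "\n")


def read_popmap(path: str | os.PathLike) -> PopulationMap:
    """Read a 3-column TSV ``individual<TAB>population<TAB>group`` (header required)."""
    ind2pop: dict[str, str] = {}
    pop2grp: dict[str, str] = {}
    with open(os.fspath(path), "rt") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3:
            raise ValueError("population map must have 3 tab-separated columns with a header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"population map line {lineno}: expected 3 columns")
            ind, pop, grp = parts[0], parts[1], parts[2]
            if ind in ind2pop:
                raise ValueError(f"population map line {lineno}: duplicate individual {ind!r}")
            if pop in pop2grp and pop2grp[pop] != grp:
                raise ValueError(
                    f"population map line {lineno}: population {pop!r} assigned to two groups"
                )
            ind2pop[ind] = pop
            pop2grp[pop] = grp
    return PopulationMap(ind2pop, pop2grp)


def write_popmap(popmap: PopulationMap, path: str | os.PathLike) -> None:
    with open(os.fspath(path), "wt") as fh:
        fh.write("individual\tpopulation\tgroup\n")
        for ind, pop in popmap.individual_to_population.items():
            fh.write(f"{ind}\t{pop}\t{popmap.population_to_group[pop]}\n")


def allele_frequency(
    gm: GenotypeMatrix, pop: str, popmap: PopulationMap
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus ALT-allele frequency and observed allele count for one population.

    Frequencies are over non-missing genotypes only; allele count is twice the
    number of non-missing diploids. Loci with no non-missing call get
    frequency ``nan`` and count 0 (the caller decides its policy for them).
    """
    idx = popmap.indices(gm, pop)
    if len(popmap.members(pop)) == 0:
        raise KeyError(f"population {pop!r} has no members")
    return dosage_frequency(gm.dosages[idx])


def dosage_frequency(dos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ALT frequency and allele count per column of a dosage sub-matrix."""
    dos = np.asarray(dos)
    called = dos != MISSING
    counts = 2 * called.sum(axis=0)
    alt = np.where(called, dos, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(counts > 0, alt / np.maximum(counts, 1), np.nan)
    return freq, counts
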