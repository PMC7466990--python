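"""Synthetic genotype datasets with known ground truth.

Emulates the study design this package targets: three diverged source gene
pools (wild graylag-like, European-domestic-like, Chinese-domestic-like),
populations of 5–15 diploids drawn from those pools or from admixtures of
them, on the order of 10^4 biallelic SNPs over ~10^6 callable sites, with
i.i.d. per-genotype missingness. Every generated dataset carries a
ground-truth record (population frequencies, admixture proportions,
scenario) sufficient to recompute each expected statistic independently.

Two frequency models are available: a Balding–Nichols approximation (each
pool's allele frequency is a Beta draw around the ancestral frequency with
a drift parameter F) for fast property tests, and a coalescent mode that
draws locus configurations from the expected joint SFS of the two-deme
divergence model for recovery tests.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from goosepop.genotype_io import (
    MISSING,
    GenotypeMatrix,
    LocusRecord,
    PopulationMap,
)

CLUSTERS = ("wild", "dom_eu", "dom_cn")

#: Balding–Nichols drift parameters per gene pool; chosen so that pairwise
#: wild/European-domestic differentiation lands near F_ST ~ 0.2 and the
#: Chinese-like pool is the most diverged, mirroring the study system.
DEFAULT_CLUSTER_F = {"wild": 0.06, "dom_eu": 0.11, "dom_cn": 0.32}
#: extra within-pool drift separating populations of the same pool; breeds
#: drift far more than wild flocks (breed formation), mirroring the much
#: higher among-breed than among-wild-population differentiation
DEFAULT_POP_F = {"wild": 0.09, "dom_eu": 0.17, "dom_cn": 0.17, "admixed": 0.03}


@dataclass(frozen=True)
class PopSpec:
    """One synthetic population: either a pure draw from a cluster or an
    alpha:(1-alpha) mixture of two clusters."""

    name: str
    group: str  # wild / domestic_european / domestic_chinese
    n_individuals: int
    cluster: str = "wild"
    admixture: tuple[str, str, float] | None = None  # (src1, src2, alpha)

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("sample sizes must be >= 1")
        if self.admixture is not None:
            s1, s2, alpha = self.admixture
            if s1 not in CLUSTERS or s2 not in CLUSTERS:
                raise ValueError("admixture sources must be known clusters")
            if not 0.0 <= alpha <= 1.0:
                raise ValueError("admixture proportion must be in [0, 1]")
        elif self.cluster not in CLUSTERS:
            raise ValueError(f"unknown cluster {self.cluster!r}")


@dataclass
class SynthConfig:
    populations: list[PopSpec]
    n_loci: int = 10_000
    total_sites: int = 1_000_000
    missingness: float = 0.05
    seed: int = 0
    frequency_model: str = "balding_nichols"
    cluster_f: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLUSTER_F))
    pop_f: float | dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_POP_F)
    )

    def __post_init__(self) -> None:
        if not self.populations:
            raise ValueError("at least one population is required")
        if not 0.0 <= self.missingness <= 0.5:
            raise ValueError("missingness must be in [0, 0.5]")
        if self.n_loci < 1 or self.total_sites < self.n_loci:
            raise ValueError("need n_loci >= 1 and total_sites >= n_loci")
        if self.frequency_model not in ("balding_nichols", "coalescent"):
            raise ValueError("frequency_model must be balding_nichols or coalescent")
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("population names must be unique")


def default_config(seed: int = 0, n_loci: int = 10_000, missingness: float = 0.05) -> SynthConfig:
    """A study-like scenario: two wild populations, two European-domestic
    breeds, one Chinese-like population, and one 50/50 admixed breed."""
    pops = [
        PopSpec("wild_a", "wild", 12, cluster="wild"),
        PopSpec("wild_b", "wild", 9, cluster="wild"),
        PopSpec("breed_a", "domestic_european", 10, cluster="dom_eu"),
        PopSpec("breed_b", "domestic_european", 7, cluster="dom_eu"),
        PopSpec("chinese", "domestic_chinese", 8, cluster="dom_cn"),
        PopSpec(
            "hybrid_breed",
            "domestic_european",
            8,
            admixture=("dom_eu", "dom_cn", 0.5),
        ),
    ]
    return SynthConfig(populations=pops, n_loci=n_loci, missingness=missingness, seed=seed)


def _cluster_frequencies(config: SynthConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Per-cluster allele frequencies under the configured frequency model."""
    if config.frequency_model == "balding_nichols":
        p_anc = rng.uniform(0.05, 0.95, size=config.n_loci)
        freqs = {}
        for cluster in CLUSTERS:
            f = config.cluster_f[cluster]
            a = p_anc * (1.0 - f) / f
            b = (1.0 - p_anc) * (1.0 - f) / f
            freqs[cluster] = rng.beta(a, b)
        return freqs
    # coalescent mode: draw wild/domestic configurations from the expected
    # joint SFS of the default divergence model; the Chinese-like pool gets
    # an independent deeper Balding-Nichols draw.
    from goosepop.demography import GOOSE_MLE, build_model, simulate_sfs

    model = build_model("changing_migration", GOOSE_MLE)
    sfs = simulate_sfs(
        model,
        n_sites=config.total_sites,
        n_reps=3000,
        seed=config.seed + 101,
        mode="expected",
        folded=False,
    )
    probs = sfs.counts / sfs.counts.sum()
    flat = rng.choice(probs.size, size=config.n_loci, p=probs.ravel())
    i, j = np.unravel_index(flat, probs.shape)
    p_w = i / sfs.n1
    p_d = j / sfs.n2
    p_anc = np.clip((p_w + p_d) / 2.0, 0.02, 0.98)
    f = config.cluster_f["dom_cn"]
    p_cn = rng.beta(p_anc * (1 - f) / f, (1 - p_anc) * (1 - f) / f)
    return {"wild": p_w, "dom_eu": p_d, "dom_cn": p_cn}


def generate_frequencies(
    config: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """(cluster frequencies, per-population frequencies) for a config."""
    rng = rng or np.random.default_rng(config.seed)
    cluster_freq = _cluster_frequencies(config, rng)
    pop_freq: dict[str, np.ndarray] = {}
    def _pop_f(spec: PopSpec) -> float:
        if not isinstance(config.pop_f, dict):
            return config.pop_f
        if spec.admixture is not None:
            # crossbred populations are recent: little drift since mixing
            # (heavy target drift would genuinely mask f3, which is a known
            # failure mode of the test, not what the generator emulates)
            return config.pop_f.get("admixed", 0.03)
        return config.pop_f[spec.cluster]

    for spec in config.populations:
        if spec.admixture is not None:
            s1, s2, alpha = spec.admixture
            base = alpha * cluster_freq[s1] + (1.0 - alpha) * cluster_freq[s2]
        else:
            base = cluster_freq[spec.cluster]
        f = _pop_f(spec)
        if f > 0:
            base_c = np.clip(base, 1e-6, 1.0 - 1e-6)
            pop_freq[spec.name] = rng.beta(
                base_c * (1 - f) / f, (1 - base_c) * (1 - f) / f
            )
        else:
            pop_freq[spec.name] = base.copy()
    return cluster_freq, pop_freq


def generate_dataset(
    config: SynthConfig,
) -> tuple[GenotypeMatrix, PopulationMap, dict]:
    """Genotypes, population map and ground truth for a synthetic scenario.

    Deterministic: the same config (including seed) reproduces the same
    dataset byte for byte.
    """
    rng = np.random.default_rng(config.seed)
    cluster_freq, pop_freq = generate_frequencies(config, rng)

    individuals: list[str] = []
    ind2pop: dict[str, str] = {}
    pop2grp: dict[str, str] = {}
    rows: list[np.ndarray] = []
    for spec in config.populations:
        pop2grp[spec.name] = spec.group
        p = pop_freq[spec.name]
        for k in range(spec.n_individuals):
            name = f"{spec.name}_{k:02d}"
            individuals.append(name)
            ind2pop[name] = spec.name
            rows.append(rng.binomial(2, p).astype(np.int8))
    dosages = np.vstack(rows)
    if config.missingness > 0:
        mask = rng.random(dosages.shape) < config.missingness
        dosages[mask] = MISSING

    bases = ("A", "C", "G", "T")
    loci = []
    for j in range(config.n_loci):
        ref, alt = rng.choice(4, size=2, replace=False)
        loci.append(
            LocusRecord(chrom="chr1", pos=j * 97 + 1, ref=bases[ref], alts=(bases[alt],))
        )
    gm = GenotypeMatrix(individuals, loci, dosages)
    popmap = PopulationMap(ind2pop, pop2grp)
    truth = {
        "config": {
            "n_loci": config.n_loci,
            "total_sites": config.total_sites,
            "missingness": config.missingness,
            "seed": config.seed,
            "frequency_model": config.frequency_model,
            "cluster_f": config.cluster_f,
            "pop_f": config.pop_f,
            "populations": [asdict(p) for p in config.populations],
        },
        "cluster_frequencies": {k: v.tolist() for k, v in cluster_freq.items()},
        "population_frequencies": {k: v.tolist() for k, v in pop_freq.items()},
        "admixture": {
            p.name: (list(p.admixture) if p.admixture else None)
            for p in config.populations
        },
    }
    return gm, popmap, truth


def write_dataset(
    config: SynthConfig, out_dir: str | os.PathLike
) -> tuple[str, str, str]:
    """Generate and write VCF + population-map TSV + ground-truth JSON."""
    from goosepop.genotype_io import write_popmap, write_vcf

    gm, popmap, truth = generate_dataset(config)
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    vcf_path = os.path.join(out_dir, "synthetic.vcf")
    map_path = os.path.join(out_dir, "popmap.tsv")
    truth_path = os.path.join(out_dir, "truth.json")
    write_vcf(gm, vcf_path)
    write_popmap(popmap, map_path)
    with open(truth_path, "wt") as fh:
        json.dump(truth, fh)
    return vcf_path, map_path, truth_path


TOY_SEED = 20200701


def generate_worked_toy() -> tuple[GenotypeMatrix, PopulationMap, dict]:
    """A deterministic 12-individual, 60-locus miniature dataset.

    Three pure populations (wild, European-domestic, Chinese-like, 3
    diploids each) plus one built-in 50/50 admixed population, with four
    planted bad loci for the filter stage: one indel, one triallelic
    locus, one invariant locus, and one heterozygosity-excess locus
    (Ho = 0.9 > 0.75).
    """
    rng = np.random.default_rng(TOY_SEED)
    config = SynthConfig(
        populations=[
            PopSpec("toy_wild", "wild", 3, cluster="wild"),
            PopSpec("toy_eu", "domestic_european", 3, cluster="dom_eu"),
            PopSpec("toy_cn", "domestic_chinese", 3, cluster="dom_cn"),
            PopSpec("toy_mix", "domestic_european", 3, admixture=("dom_eu", "dom_cn", 0.5)),
        ],
        n_loci=56,
        total_sites=5600,
        missingness=0.0,
        seed=TOY_SEED,
    )
    gm, popmap, truth = generate_dataset(config)

    # ensure the 56 clean loci are genuinely variant and within Ho bounds
    dosages = gm.dosages.copy()
    for j in range(dosages.shape[1]):
        col = dosages[:, j]
        if (col == col[0]).all():
            col[0] = 1 if col[0] != 1 else 0
        while (col == 1).mean() > 0.75:
            col[np.argmax(col == 1)] = 0

    n_ind = gm.n_individuals
    planted_dosages = np.empty((n_ind, 4), dtype=np.int8)
    planted_dosages[:, 0] = rng.binomial(2, 0.4, n_ind)  # indel locus
    planted_dosages[:, 1] = rng.binomial(2, 0.5, n_ind)  # triallelic locus
    planted_dosages[:, 2] = 0  # invariant locus
    het = np.ones(n_ind, dtype=np.int8)  # 11/12 hets -> Ho ~ 0.9
    het[0] = 0
    planted_dosages[:, 3] = het

    planted_loci = [
        LocusRecord("chr9", 11, "A", ("AT",)),  # indel
        LocusRecord("chr9", 23, "C", ("G", "T")),  # triallelic
        LocusRecord("chr9", 37, "G", ("A",)),  # invariant
        LocusRecord("chr9", 49, "T", ("C",)),  # het excess
    ]
    loci = list(gm.loci) + planted_loci
    dosages = np.hstack([dosages, planted_dosages])
    gm = GenotypeMatrix(gm.individuals, loci, dosages)
    truth["planted_bad_loci"] = {
        "indel": 1,
        "multi_allelic": 1,
        "invariant": 1,
        "heterozygosity_excess": 1,
    }
    truth["n_clean_loci"] = 56
    return gm, popmap, truth
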