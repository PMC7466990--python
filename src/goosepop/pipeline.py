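"""End-to-end pipeline orchestration with a single JSON config.

Stages run in dependency order (filter, then the per-stage statistics,
then SFS construction and demographic fitting); every stage writes its
outputs under the run directory and records parameters, seeds and wall
time in ``manifest.json``. All randomness flows from one master seed via
named substreams, so partial reruns are reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np

from goosepop import (
    FitSettings,
    akaike_weights,
    amova,
    apply_individual_filter,
    apply_site_filters,
    expected_heterozygosity,
    f3_test,
    fit_sfs,
    nj_tree,
    pairwise_distance,
    pairwise_fst,
    pca,
    read_popmap,
    read_vcf,
    welch_t_test,
    write_vcf,
)
from goosepop.genotype_io import MISSING, DOMESTIC_EUROPEAN, WILD
from goosepop.sfs import sfs_from_dosages
from goosepop.variant_filtering import site_accounting_from_report

log = logging.getLogger("goosepop.pipeline")

ALL_STAGES = ("filter", "diversity", "fst", "amova", "f3", "structure", "sfs", "fit")


@dataclass
class PipelineConfig:
    vcf: str
    popmap: str
    out_dir: str
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    seed: int = 0
    profile: str = "desk"
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s in self.stages:
            if s not in ALL_STAGES:
                raise ValueError(f"unknown stage {s!r}; valid: {ALL_STAGES}")
        for path, label in ((self.vcf, "vcf"), (self.popmap, "popmap")):
            if not os.path.exists(path):
                raise FileNotFoundError(f"{label} input not found: {path}")
        if self.profile not in ("desk", "paper", "fast"):
            raise ValueError("profile must be desk, paper or fast")

    @classmethod
    def from_json(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(**obj)


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> str:
    """Run the configured stages; returns the run directory path."""
    from goosepop import __version__

    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {
        "goosepop_version": __version__,
        "seed": config.seed,
        "profile": config.profile,
        "inputs": {
            "vcf": {"path": config.vcf, "sha256_16": _checksum(config.vcf)},
            "popmap": {"path": config.popmap, "sha256_16": _checksum(config.popmap)},
        },
        "stages": {},
    }

    gm = read_vcf(config.vcf)
    popmap = read_popmap(config.popmap)
    popmap.validate_against(gm)

    def record(stage: str, t0: float, outputs: dict) -> None:
        manifest["stages"][stage] = {
            "seed": _stage_seed(config.seed, stage),
            "wall_seconds": round(time.time() - t0, 3),
            "outputs": outputs,
            "parameters": config.overrides.get(stage, {}),
        }
        with open(os.path.join(config.out_dir, "manifest.json"), "wt") as fh:
            json.dump(manifest, fh, indent=2)
        log.info("stage %s done in %.2fs", stage, time.time() - t0)

    filter_report = None
    if "filter" in config.stages:
        t0 = time.time()
        opts = config.overrides.get("filter", {})
        gm, site_report = apply_site_filters(
            gm,
            max_het=opts.get("max_het", 0.75),
            keep_cross_species_divergent=opts.get("keep_divergent_invariant", False),
        )
        gm, ind_report = apply_individual_filter(
            gm, max_missing=opts.get("max_missing", 0.20)
        )
        filter_report = site_report
        out_vcf = os.path.join(config.out_dir, "filtered.vcf")
        write_vcf(gm, out_vcf)
        report_path = os.path.join(config.out_dir, "filter_report.json")
        with open(report_path, "wt") as fh:
            json.dump(
                {"sites": site_report.to_dict(), "individuals": ind_report.to_dict()},
                fh,
                indent=2,
            )
        record("filter", t0, {"vcf": out_vcf, "report": report_path})

    if "diversity" in config.stages:
        t0 = time.time()
        table = expected_heterozygosity(gm, popmap)
        csv_path = os.path.join(config.out_dir, "diversity.csv")
        with open(csv_path, "wt") as fh:
            fh.write("population,mean_HE,n_loci\n")
            for pop in table.populations:
                fh.write(f"{pop},{table.mean_he[pop]:.6f},{table.n_defined_loci[pop]}\n")
        outputs = {"csv": csv_path}
        wild_means = [
            table.mean_he[p] for p in popmap.populations_in_group(WILD)
        ]
        dom_means = [
            table.mean_he[p] for p in popmap.populations_in_group(DOMESTIC_EUROPEAN)
        ]
        if len(wild_means) >= 2 and len(dom_means) >= 2:
            welch = welch_t_test(np.array(wild_means), np.array(dom_means))
            welch_path = os.path.join(config.out_dir, "welch.json")
            with open(welch_path, "wt") as fh:
                json.dump(
                    {
                        "t": welch.t,
                        "df": welch.df,
                        "p_value": welch.p_value,
                        "mean_wild": welch.mean_x,
                        "mean_domestic_european": welch.mean_y,
                    },
                    fh,
                    indent=2,
                )
            outputs["welch"] = welch_path
        record("diversity", t0, outputs)

    if "fst" in config.stages:
        t0 = time.time()
        fst = pairwise_fst(gm, popmap)
        csv_path = os.path.join(config.out_dir, "fst.csv")
        with open(csv_path, "wt") as fh:
            fh.write("," + ",".join(fst.populations) + "\n")
            for i, p in enumerate(fst.populations):
                fh.write(p + "," + ",".join(f"{v:.6f}" for v in fst.values[i]) + "\n")
        record("fst", t0, {"csv": csv_path})

    if "amova" in config.stages:
        t0 = time.time()
        opts = config.overrides.get("amova", {})
        res = amova(
            gm,
            popmap,
            n_perm=opts.get("n_perm", 999),
            seed=_stage_seed(config.seed, "amova"),
        )
        path = os.path.join(config.out_dir, "amova.json")
        with open(path, "wt") as fh:
            json.dump(res.to_dict(), fh, indent=2)
        record("amova", t0, {"json": path})

    if "f3" in config.stages:
        t0 = time.time()
        opts = config.overrides.get("f3", {})
        triples = opts.get("triples", [])
        results = []
        for target, src_a, src_b in triples:
            r = f3_test(
                gm, target, src_a, src_b, popmap,
                block_size=opts.get("block_size", 500),
            )
            results.append(
                {
                    "target": target,
                    "source_a": src_a,
                    "source_b": src_b,
                    "f3": r.f3,
                    "se": r.se,
                    "z": r.z,
                    "n_blocks": r.n_blocks,
                    "n_loci_used": r.n_loci_used,
                }
            )
        path = os.path.join(config.out_dir, "f3.json")
        with open(path, "wt") as fh:
            json.dump(results, fh, indent=2)
        record("f3", t0, {"json": path})

    if "structure" in config.stages:
        t0 = time.time()
        res = pca(gm)
        scores_path = os.path.join(config.out_dir, "pca_scores.csv")
        with open(scores_path, "wt") as fh:
            k = res.scores.shape[1]
            fh.write("individual," + ",".join(f"PC{i+1}" for i in range(k)) + "\n")
            for ind, row in zip(res.individuals, res.scores):
                fh.write(ind + "," + ",".join(f"{v:.6f}" for v in row) + "\n")
        dm = pairwise_distance(gm)
        tree_path = os.path.join(config.out_dir, "nj_tree.nwk")
        with open(tree_path, "wt") as fh:
            fh.write(nj_tree(dm) + "\n")
        pca_meta = os.path.join(config.out_dir, "pca.json")
        with open(pca_meta, "wt") as fh:
            json.dump(
                {
                    "n_significant_axes": res.n_significant,
                    "tw_p_values": res.tw_p_values.tolist(),
                    "distance_metric": "allele_sharing",
                },
                fh,
                indent=2,
            )
        record("structure", t0, {"scores": scores_path, "tree": tree_path, "meta": pca_meta})

    observed_sfs = None
    if "sfs" in config.stages:
        t0 = time.time()
        opts = config.overrides.get("sfs", {})
        wild_pops = opts.get("wild_populations") or popmap.populations_in_group(WILD)
        dom_pops = opts.get("domestic_populations") or popmap.populations_in_group(
            DOMESTIC_EUROPEAN
        )
        wild_idx = np.concatenate([popmap.indices(gm, p) for p in wild_pops])
        dom_idx = np.concatenate([popmap.indices(gm, p) for p in dom_pops])
        complete = ~(gm.dosages[np.concatenate([wild_idx, dom_idx])] == MISSING).any(axis=0)
        covered_bp = opts.get("covered_bp", config.overrides.get("covered_bp"))
        if covered_bp is None:
            covered_bp = 100 * gm.n_loci  # GBS-tag scale default: ~100 bp per locus
        if filter_report is not None:
            accounts = site_accounting_from_report(
                filter_report, covered_bp, int(complete.sum())
            )
            total = accounts.total_sites
        else:
            total = int(round(covered_bp * complete.mean()))
        observed_sfs = sfs_from_dosages(
            gm.dosages[wild_idx][:, complete],
            gm.dosages[dom_idx][:, complete],
            total_sites=total,
        )
        path = os.path.join(config.out_dir, "observed_sfs.json")
        observed_sfs.to_json(path)
        record("sfs", t0, {"json": path})

    if "fit" in config.stages:
        if observed_sfs is None:
            raise ValueError("fit stage requires the sfs stage")
        t0 = time.time()
        opts = config.overrides.get("fit", {})
        settings = FitSettings.profile(opts.get("profile", config.profile))
        models = opts.get("models", ["no_migration", "constant_migration", "changing_migration"])
        fits = [
            fit_sfs(
                observed_sfs,
                m,
                settings=settings,
                seed=_stage_seed(config.seed, f"fit:{m}"),
                mu=opts.get("mu", 1.38e-7),
            )
            for m in models
        ]
        if len(fits) >= 2:
            akaike_weights(fits)
        path = os.path.join(config.out_dir, "fits.json")
        with open(path, "wt") as fh:
            json.dump([f.to_dict() for f in fits], fh, indent=2)
        record("fit", t0, {"json": path})

    return config.out_dir
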