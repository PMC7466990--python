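"""Two-population site-frequency spectra with an explicit monomorphic class.

The joint SFS counts sites by (allele count in the wild sample, allele count
in the domestic sample). Unlike many SFS containers, the monomorphic class
is first-class here: the demographic composite likelihood needs the number
of callable sites that show no variation, because with a fixed mutation rate
the ratio of polymorphic to monomorphic sites is what pins down absolute
population sizes and times.

Folding merges each cell with its complementary orientation, keeping the
one whose pooled (summed over both samples) allele count does not exceed
half the pooled sample size; exact ties receive half the mass from each
orientation. Sites fixed for the alternative orientation, like sites with
no variation, land in the monomorphic class.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np


@dataclass
class Sfs2D:
    """Joint SFS over two samples of ``n1`` and ``n2`` allele copies.

    ``counts[i, j]`` holds sites with i copies in sample 1 (wild) and j in
    sample 2 (domestic); the (0, 0) cell is always empty — invariant sites
    live in ``monomorphic``. In an unfolded spectrum the (n1, n2) cell may
    hold fixed-derived sites; folding moves them to the monomorphic class.
    """

    counts: np.ndarray  # shape (n1 + 1, n2 + 1), non-negative
    monomorphic: float
    folded: bool

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if (self.counts < 0).any() or self.monomorphic < 0:
            raise ValueError("SFS counts must be non-negative")
        if self.counts[0, 0] != 0:
            raise ValueError("the (0, 0) cell belongs to the monomorphic class")
        if self.folded:
            n1, n2 = self.n1, self.n2
            half = (n1 + n2) / 2
            idx_i, idx_j = np.nonzero(self.counts)
            if ((idx_i + idx_j) > half).any():
                raise ValueError(
                    "folded spectrum has mass above half the pooled sample size"
                )

    @property
    def n1(self) -> int:
        return self.counts.shape[0] - 1

    @property
    def n2(self) -> int:
        return self.counts.shape[1] - 1

    @property
    def polymorphic(self) -> float:
        return float(self.counts.sum())

    @property
    def total_sites(self) -> float:
        return self.polymorphic + self.monomorphic

    def normalized(self) -> tuple[np.ndarray, float]:
        """Cell probabilities and the monomorphic probability (sum to 1)."""
        total = self.total_sites
        if total <= 0:
            raise ValueError("empty spectrum cannot be normalized")
        return self.counts / total, self.monomorphic / total

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | os.PathLike) -> None:
        obj = {
            "n1": self.n1,
            "n2": self.n2,
            "folded": self.folded,
            "monomorphic": self.monomorphic,
            "counts": self.counts.tolist(),
        }
        with open(os.fspath(path), "wt") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "Sfs2D":
        with open(os.fspath(path), "rt") as fh:
            obj = json.load(fh)
        counts = np.asarray(obj["counts"], dtype=float)
        if counts.shape != (obj["n1"] + 1, obj["n2"] + 1):
            raise ValueError("JSON SFS dimensions are inconsistent")
        return cls(counts=counts, monomorphic=float(obj["monomorphic"]), folded=obj["folded"])

    def to_obs(self, path: str | os.PathLike) -> None:
        """Write the fastsimcoal-style joint-SFS text dialect.

        Header line "1 observations", a column-label line, then one
        labelled row per sample-1 allele count. The monomorphic class is
        stored in the (0, 0) cell, as that dialect expects.
        """
        with open(os.fspath(path), "wt") as fh:
            fh.write("1 observations\n")
            fh.write("\t" + "\t".join(f"d0_{j}" for j in range(self.n2 + 1)) + "\n")
            grid = self.counts.copy()
            grid[0, 0] = self.monomorphic
            for i in range(self.n1 + 1):
                row = "\t".join(f"{v:.10g}" for v in grid[i])
                fh.write(f"d1_{i}\t{row}\n")

    @classmethod
    def from_obs(cls, path: str | os.PathLike, folded: bool = True) -> "Sfs2D":
        with open(os.fspath(path), "rt") as fh:
            lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
        if not lines[0].lower().endswith("observations"):
            raise ValueError("missing 'observations' header line")
        rows = []
        for ln in lines[2:]:
            parts = ln.split()
            rows.append([float(x) for x in parts[1:]])
        grid = np.asarray(rows, dtype=float)
        mono = float(grid[0, 0])
        grid[0, 0] = 0.0
        return cls(counts=grid, monomorphic=mono, folded=folded)


def fold(sfs: Sfs2D) -> Sfs2D:
    """Fold an unfolded joint spectrum by the pooled minor allele."""
    if sfs.folded:
        raise ValueError("spectrum is already folded")
    n1, n2 = sfs.n1, sfs.n2
    pooled_n = n1 + n2
    src = sfs.counts.copy()
    mono = sfs.monomorphic + src[n1, n2]  # fixed-derived shows no minor allele
    src[n1, n2] = 0.0
    pooled = np.add.outer(np.arange(n1 + 1), np.arange(n2 + 1))
    low = 2 * pooled < pooled_n
    high = 2 * pooled > pooled_n
    tie = ~low & ~high
    flipped = src[::-1, ::-1]
    out = (
        src * low
        + flipped * high[::-1, ::-1]
        + 0.5 * (src * tie + flipped * tie[::-1, ::-1])
    )
    return Sfs2D(counts=out, monomorphic=mono, folded=True)


def sfs_from_dosages(
    dos_wild: np.ndarray, dos_dom: np.ndarray, total_sites: float
) -> Sfs2D:
    """Folded joint SFS from complete-case dosage sub-matrices.

    Sites with any missing genotype must be excluded beforehand (the
    spectrum requires full allele counts); ``total_sites`` supplies the
    callable-site denominator for the monomorphic class.
    """
    if (dos_wild < 0).any() or (dos_dom < 0).any():
        raise ValueError("dosage matrices must be complete (no missing calls)")
    n1 = 2 * dos_wild.shape[0]
    n2 = 2 * dos_dom.shape[0]
    i_counts = dos_wild.sum(axis=0).astype(int)
    j_counts = dos_dom.sum(axis=0).astype(int)
    counts = np.zeros((n1 + 1, n2 + 1))
    np.add.at(counts, (i_counts, j_counts), 1.0)
    mono = counts[0, 0] + counts[n1, n2]
    counts[0, 0] = 0.0
    counts[n1, n2] = 0.0
    unfolded = Sfs2D(
        counts=counts,
        monomorphic=float(mono + (total_sites - counts.sum() - mono)),
        folded=False,
    )
    return fold(unfolded)
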