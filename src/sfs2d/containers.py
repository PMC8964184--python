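"""Core data containers: genotype matrices, population maps, joint spectra."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["MISSING", "DEPTH_UNKNOWN", "PopMap", "GenotypeMatrix", "JointSFS"]

MISSING = -1        # genotype dosage code for a missing call
DEPTH_UNKNOWN = -1  # depth code when the VCF carries no per-genotype DP


class PopMap:
    """Ordered mapping individual ID -> population label.

    Individual IDs are unique; every named population has at least one
    member; labels are non-empty.
    """

    def __init__(self, entries):
        entries = dict(entries)
        if not entries:
            raise ValueError("population map is empty")
        for ind, pop in entries.items():
            if not str(pop):
                raise ValueError(f"empty population label for {ind!r}")
        self.entries = entries

    def __len__(self):
        return len(self.entries)

    def __getitem__(self, individual):
        return self.entries[individual]

    def __contains__(self, individual):
        return individual in self.entries

    def __eq__(self, other):
        return isinstance(other, PopMap) and self.entries == other.entries

    @property
    def individuals(self):
        return list(self.entries)

    def populations(self):
        """Population labels in first-appearance order."""
        seen = []
        for pop in self.entries.values():
            if pop not in seen:
                seen.append(pop)
        return seen

    def members(self, pop):
        if pop not in self.populations():
            raise KeyError(f"population {pop!r} not in map")
        return [ind for ind, p in self.entries.items() if p == pop]


@dataclass
class GenotypeMatrix:
    """Per-site biallelic diploid genotypes with depth and missingness.

    ``genotypes`` holds alternate-allele dosage in {0, 1, 2} with
    :data:`MISSING` (-1) for no-calls; ``depths`` the per-genotype read depth
    with :data:`DEPTH_UNKNOWN` (-1) where the source carried none.  One row
    per site; ``locus`` is the RAD-locus identifier (the VCF CHROM), and
    ``pos`` the 1-based site position within the locus.
    """

    locus: np.ndarray        # object array of str, shape (n_sites,)
    pos: np.ndarray          # int64, 1-based
    ref: np.ndarray          # object array of str
    alt: np.ndarray          # object array of str
    genotypes: np.ndarray    # int8, shape (n_sites, n_individuals)
    depths: np.ndarray       # int32, same shape
    individuals: list        # ordered sample IDs

    def __post_init__(self):
        self.locus = np.asarray(self.locus, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.depths = np.asarray(self.depths, dtype=np.int32)
        if self.genotypes.shape != self.depths.shape:
            raise ValueError("genotypes and depths must share shape")
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (sites x individuals)")
        if self.genotypes.shape[1] != len(self.individuals):
            raise ValueError("individual count mismatch")
        n = self.genotypes.shape[0]
        for arr, name in ((self.locus, "locus"), (self.pos, "pos"),
                          (self.ref, "ref"), (self.alt, "alt")):
            if len(arr) != n:
                raise ValueError(f"{name} length != number of sites")
        bad = ~np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype dosages must be in {0,1,2} or missing")

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[1]

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.locus.copy(), self.pos.copy(),
                              self.ref.copy(), self.alt.copy(),
                              self.genotypes.copy(), self.depths.copy(),
                              list(self.individuals))

    def take_sites(self, index) -> "GenotypeMatrix":
        """New matrix restricted to the given site indices (order kept)."""
        index = np.asarray(index)
        return GenotypeMatrix(self.locus[index], self.pos[index],
                              self.ref[index], self.alt[index],
                              self.genotypes[index], self.depths[index],
                              list(self.individuals))

    def columns_for(self, popmap: PopMap, pop: str) -> np.ndarray:
        """Column indices of the members of ``pop`` (membership-checked)."""
        members = set(popmap.members(pop))
        cols = [i for i, ind in enumerate(self.individuals) if ind in members]
        missing = members - set(self.individuals)
        if missing:
            raise KeyError(
                f"individuals in population map absent from matrix: "
                f"{sorted(missing)}")
        return np.asarray(cols, dtype=np.intp)


@dataclass
class JointSFS:
    """A 2-D joint site-frequency spectrum.

    ``counts[i, j]`` is the (possibly expected, hence real-valued) number of
    sites with derived-allele count ``i`` in population 1 and ``j`` in
    population 2, on samples of ``n1`` and ``n2`` alleles.  Masked cells
    (always the fixed corners, plus the redundant half after folding) hold 0.
    """

    counts: np.ndarray
    folded: bool = False
    mask: Optional[np.ndarray] = None
    pop_ids: tuple = ("pop1", "pop2")

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("JointSFS counts must be 2-D")
        if self.mask is None:
            self.mask = np.zeros(self.counts.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.counts.shape:
                raise ValueError("mask shape mismatch")
        # fixed corners are never informative
        self.mask[0, 0] = True
        self.mask[-1, -1] = True
        self.counts[self.mask] = 0.0

    @property
    def n1(self) -> int:
        return self.counts.shape[0] - 1

    @property
    def n2(self) -> int:
        return self.counts.shape[1] - 1

    @property
    def shape(self) -> tuple:
        return self.counts.shape

    def sum(self) -> float:
        """Total unmasked mass."""
        return float(self.counts[~self.mask].sum())

    def copy(self) -> "JointSFS":
        return JointSFS(self.counts.copy(), self.folded, self.mask.copy(),
                        tuple(self.pop_ids))

    def fold(self) -> "JointSFS":
        from .sfs import fold
        return fold(self)

    def __eq__(self, other):
        return (isinstance(other, JointSFS)
                and self.folded == other.folded
                and tuple(self.pop_ids) == tuple(other.pop_ids)
                and self.counts.shape == other.counts.shape
                and np.array_equal(self.mask, other.mask)
                and np.allclose(self.counts, other.counts))
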