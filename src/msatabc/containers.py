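"""Core in-memory containers for diploid microsatellite data.

Genotypes are stored as repeat counts in a dense integer array of shape
``(n_individuals, n_loci, 2)``; missing alleles are coded ``MISSING`` (-1).
Populations are contiguous blocks of rows, in a fixed order.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = -1


@dataclass(frozen=True)
class LocusSpec:
    """A microsatellite locus: its ancestral repeat count and allele window.

    The mutational state space is ``allowed_states`` contiguous repeat counts
    centred on ``ancestral_size``; mutations falling outside the window are
    reflected at the boundary. ``motif`` (repeat-unit length in bp) is
    informational only — all arithmetic is in repeat units.
    """

    name: str
    ancestral_size: int = 20
    allowed_states: int = 40
    motif: int = 2

    def __post_init__(self) -> None:
        if self.allowed_states < 2:
            raise ValueError(f"locus {self.name}: allowed_states must be >= 2")
        lo, hi = self.window
        if not (lo <= self.ancestral_size <= hi):
            raise ValueError(f"locus {self.name}: ancestral size outside allele window")
        if lo < 1:
            raise ValueError(
                f"locus {self.name}: allele window extends below 1 repeat "
                f"(ancestral_size too small for allowed_states)"
            )

    @property
    def window(self) -> tuple[int, int]:
        lo = self.ancestral_size - self.allowed_states // 2 + 1
        return lo, lo + self.allowed_states - 1


@dataclass
class GenotypeDataset:
    """Diploid genotypes for several populations at shared loci.

    Attributes
    ----------
    populations : list of str
        Ordered population labels.
    pop_sizes : ndarray of int
        Number of individuals per population; rows of ``genotypes`` are
        grouped by population in this order.
    loci : list of LocusSpec
    genotypes : ndarray, shape (n_individuals, n_loci, 2)
        Allele sizes in repeat units; ``MISSING`` marks a missing allele.
    individual_ids : list of str, optional
    """

    populations: list[str]
    pop_sizes: np.ndarray
    loci: list[LocusSpec]
    genotypes: np.ndarray
    individual_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pop_sizes = np.asarray(self.pop_sizes, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int16)
        if len(self.populations) != len(self.pop_sizes):
            raise ValueError("populations and pop_sizes length mismatch")
        if self.genotypes.ndim != 3 or self.genotypes.shape[2] != 2:
            raise ValueError("genotypes must have shape (n_individuals, n_loci, 2)")
        if self.genotypes.shape[0] != int(self.pop_sizes.sum()):
            raise ValueError("genotype rows do not match total sample size")
        if self.genotypes.shape[1] != len(self.loci):
            raise ValueError("genotype columns do not match locus count")
        if not self.individual_ids:
            self.individual_ids = [
                f"{pop}_{i + 1}"
                for pop, size in zip(self.populations, self.pop_sizes)
                for i in range(size)
            ]

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def pop_offsets(self) -> np.ndarray:
        """Start row of each population block (length n_populations + 1)."""
        return np.concatenate([[0], np.cumsum(self.pop_sizes)])

    def pop_slice(self, i: int) -> slice:
        off = self.pop_offsets
        return slice(int(off[i]), int(off[i + 1]))

    def pop_genotypes(self, i: int) -> np.ndarray:
        """Genotypes of population ``i``, shape (n_i, n_loci, 2)."""
        return self.genotypes[self.pop_slice(i)]

    def allele_counts(self, i: int, max_state: int | None = None) -> np.ndarray:
        """Per-locus allele count table for population ``i``.

        Returns an integer array of shape ``(n_loci, max_state + 1)`` where
        entry ``[l, a]`` counts gene copies of size ``a`` at locus ``l``
        (missing alleles excluded).
        """
        if max_state is None:
            max_state = max(spec.window[1] for spec in self.loci)
        g = self.pop_genotypes(i)
        out = np.zeros((self.n_loci, max_state + 1), dtype=np.int64)
        for l in range(self.n_loci):
            alleles = g[:, l, :].ravel()
            alleles = alleles[alleles != MISSING]
            out[l] = np.bincount(alleles, minlength=max_state + 1)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.populations == other.populations
            and np.array_equal(self.pop_sizes, other.pop_sizes)
            and [s.name for s in self.loci] == [s.name for s in other.loci]
            and np.array_equal(self.genotypes, other.genotypes)
        )
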