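"""Core in-memory containers for phased haplotype panels and per-site metadata.

The central object is :class:`HaplotypePanel`: a phased, ancestral-polarized
haplotype matrix (0 = ancestral, 1 = derived) for diploid samples grouped by
species.  Sample ``i`` owns haplotype rows ``2*i`` and ``2*i + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["HaplotypePanel", "SiteTable"]


@dataclass
class SiteTable:
    """Per-site metadata: coordinates plus optional QC INFO fields.

    ``df`` holds at least columns ``chrom`` and ``pos`` (1-based, sorted
    within chromosome); QC-related INFO fields (MQ, MQ0F, ExcHet, ...) are
    additional columns when present.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if not {"chrom", "pos"}.issubset(self.df.columns):
            raise ValueError("SiteTable requires 'chrom' and 'pos' columns")

    @property
    def n_sites(self) -> int:
        return len(self.df)

    def positions(self, chrom: str) -> np.ndarray:
        return self.df.loc[self.df["chrom"] == chrom, "pos"].to_numpy()


@dataclass
class HaplotypePanel:
    """Phased, polarized haplotypes for a multi-species sample panel.

    Parameters
    ----------
    haplotypes
        int8 array of shape (2 * n_samples, n_sites); 0 ancestral, 1 derived.
    samples
        Sample identifiers, length n_samples.
    species
        Species assignment per sample, length n_samples.
    chrom, pos
        Per-site chromosome name and 1-based position, sorted by
        (chrom, pos) with unique positions within a chromosome.
    chrom_lengths
        Mapping chromosome -> length in bp.
    """

    haplotypes: np.ndarray
    samples: list[str]
    species: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.species = np.asarray(self.species)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be 2-D")
        if self.haplotypes.shape[0] != 2 * len(self.samples):
            raise ValueError("haplotype rows must equal 2 * n_samples")
        if self.haplotypes.shape[1] != self.pos.size:
            raise ValueError("haplotype columns must match number of sites")
        if self.species.size != len(self.samples):
            raise ValueError("one species label per sample required")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if p.size != np.unique(p).size:
                raise ValueError(f"duplicate positions on {c}")
            if np.any(np.diff(p) < 0):
                raise ValueError(f"positions not sorted on {c}")

    # -- basic shape --------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def species_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.species:
            seen.setdefault(str(s), None)
        return list(seen)

    # -- indexing helpers ---------------------------------------------------

    def sample_indices(self, species: str) -> np.ndarray:
        """Sample indices belonging to one species."""
        return np.flatnonzero(self.species == species)

    def haplotype_indices(self, species: str) -> np.ndarray:
        """Haplotype row indices belonging to one species."""
        si = self.sample_indices(species)
        return np.sort(np.concatenate([2 * si, 2 * si + 1]))

    def site_index(self, chrom: str, pos: int) -> int:
        hits = np.flatnonzero((self.chrom == chrom) & (self.pos == pos))
        if hits.size == 0:
            raise KeyError(f"no site at {chrom}:{pos}")
        return int(hits[0])

    def nearest_site(self, chrom: str, pos: int) -> int:
        """Index of the site on ``chrom`` closest to ``pos``."""
        cand = np.flatnonzero(self.chrom == chrom)
        if cand.size == 0:
            raise KeyError(f"no sites on {chrom}")
        return int(cand[np.argmin(np.abs(self.pos[cand] - pos))])

    # -- derived quantities -------------------------------------------------

    def dosages(self) -> np.ndarray:
        """Diploid derived-allele dosage matrix, shape (n_samples, n_sites)."""
        h = self.haplotypes
        return (h[0::2, :] + h[1::2, :]).astype(np.int8)

    def derived_frequency(self, species: str | None = None) -> np.ndarray:
        """Derived-allele frequency per site, overall or within one species."""
        if species is None:
            return self.haplotypes.mean(axis=0)
        rows = self.haplotype_indices(species)
        return self.haplotypes[rows, :].mean(axis=0)

    def subset_species(self, keep: list[str]) -> "HaplotypePanel":
        """Panel restricted to the given species (sample order preserved)."""
        mask = np.isin(self.species, keep)
        si = np.flatnonzero(mask)
        rows = np.sort(np.concatenate([2 * si, 2 * si + 1]))
        return HaplotypePanel(
            haplotypes=self.haplotypes[rows, :].copy(),
            samples=[self.samples[i] for i in si],
            species=self.species[si].copy(),
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            chrom_lengths=dict(self.chrom_lengths),
        )

    def copy(self) -> "HaplotypePanel":
        return HaplotypePanel(
            haplotypes=self.haplotypes.copy(),
            samples=list(self.samples),
            species=self.species.copy(),
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            chrom_lengths=dict(self.chrom_lengths),
        )

    def __eq__(self, other: object) -> bool:  # bit-identity, for determinism tests
        if not isinstance(other, HaplotypePanel):
            return NotImplemented
        return (
            np.array_equal(self.haplotypes, other.haplotypes)
            and self.samples == other.samples
            and np.array_equal(self.species, other.species)
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and self.chrom_lengths == other.chrom_lengths
        )
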