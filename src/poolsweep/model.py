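"""Core data model for pooled time-series variant data.

The central container is :class:`VariantTable`, a sites x samples grid of
ref/alt read counts from pooled sequencing (pool-seq). Allele frequencies are
derived quantities: a frequency is only defined where sequencing depth reaches
``min_depth`` reads; elsewhere it is *missing* (NaN), never zero. Downstream
filters rely on that distinction between "no data" and "allele absent".

Coordinates are 1-based inclusive throughout the public data model.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

BASES = ("A", "C", "G", "T")


class Treatment(str, enum.Enum):
    """Demographic treatment of an experimental replicate."""

    WEAK_DEMOGRAPHY = "weak_demography"
    STRONG_DEMOGRAPHY = "strong_demography"
    ANCESTOR = "ancestor"


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one pooled sequencing library.

    Parameters
    ----------
    sample_id
        Unique library identifier.
    replicate_id
        Evolutionary replicate the library was drawn from.
    treatment
        Demographic treatment; ancestors carry no time point.
    day
        Days since the start of the experiment (required unless ancestor).
    batch_id
        Sequencing batch (machine/run); artifact detection groups by batch.
    """

    sample_id: str
    replicate_id: str
    treatment: Treatment
    day: Optional[int] = None
    batch_id: str = "batch0"

    def __post_init__(self) -> None:
        object.__setattr__(self, "treatment", Treatment(self.treatment))
        if self.treatment is not Treatment.ANCESTOR:
            if self.day is None:
                raise ValueError(
                    f"sample {self.sample_id!r}: day is required for "
                    f"non-ancestor samples"
                )
            if self.day < 0:
                raise ValueError(f"sample {self.sample_id!r}: day must be >= 0")

    @property
    def is_ancestor(self) -> bool:
        return self.treatment is Treatment.ANCESTOR


@dataclass(frozen=True)
class VariantSite:
    """One biallelic SNP. Two alt bases at a position are two sites."""

    contig: str
    pos: int
    ref_base: str
    alt_base: str
    qual: float = 0.0

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be 1-based positive, got {self.pos}")
        if self.ref_base not in BASES:
            raise ValueError(f"ref_base must be one of {BASES}, got {self.ref_base!r}")
        if self.alt_base not in BASES:
            raise ValueError(f"alt_base must be one of {BASES}, got {self.alt_base!r}")
        if self.alt_base == self.ref_base:
            raise ValueError("alt_base must differ from ref_base")
        if self.qual < 0:
            raise ValueError("qual must be non-negative")

    @property
    def key(self) -> tuple:
        return (self.contig, self.pos, self.alt_base)


@dataclass
class VariantTable:
    """Sites x samples matrix of pooled ref/alt read counts.

    ``ref_counts`` and ``alt_counts`` are integer arrays of shape
    ``(n_sites, n_samples)``. The allele frequency matrix :attr:`af` is
    ``alt/(ref+alt)`` where depth >= ``min_depth`` and NaN elsewhere.
    """

    sites: list[VariantSite]
    samples: list[SampleMeta]
    ref_counts: np.ndarray
    alt_counts: np.ndarray
    min_depth: int = 10

    def __post_init__(self) -> None:
        self.ref_counts = np.asarray(self.ref_counts, dtype=np.int64)
        self.alt_counts = np.asarray(self.alt_counts, dtype=np.int64)
        shape = (len(self.sites), len(self.samples))
        if self.ref_counts.shape != shape or self.alt_counts.shape != shape:
            raise ValueError(
                f"count grids must have shape {shape}, got "
                f"{self.ref_counts.shape} and {self.alt_counts.shape}"
            )
        if (self.ref_counts < 0).any() or (self.alt_counts < 0).any():
            raise ValueError("read counts must be non-negative")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in table")
        keys = [s.key for s in self.sites]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (contig, pos, alt) site in table")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def depth(self) -> np.ndarray:
        return self.ref_counts + self.alt_counts

    @property
    def af(self) -> np.ndarray:
        """Allele-frequency matrix; NaN where depth < min_depth."""
        depth = self.depth
        with np.errstate(divide="ignore", invalid="ignore"):
            freq = self.alt_counts / depth
        freq = np.where(depth >= self.min_depth, freq, np.nan)
        return freq

    def missing_fraction(self) -> np.ndarray:
        """Per-site fraction of samples with undefined allele frequency."""
        return np.isnan(self.af).mean(axis=1)

    def sample_index(self, sample_id: str) -> int:
        for i, s in enumerate(self.samples):
            if s.sample_id == sample_id:
                return i
        raise KeyError(sample_id)

    def subset_sites(self, mask: Sequence[bool]) -> "VariantTable":
        mask = np.asarray(mask, dtype=bool)
        return VariantTable(
            sites=[s for s, keep in zip(self.sites, mask) if keep],
            samples=list(self.samples),
            ref_counts=self.ref_counts[mask],
            alt_counts=self.alt_counts[mask],
            min_depth=self.min_depth,
        )

    def replicate_samples(
        self, include_ancestors: bool = False
    ) -> dict[str, list[int]]:
        """Sample column indices per replicate, ordered by day."""
        groups: dict[str, list[int]] = {}
        for i, s in enumerate(self.samples):
            if s.is_ancestor and not include_ancestors:
                continue
            groups.setdefault(s.replicate_id, []).append(i)
        for rep in groups:
            groups[rep].sort(key=lambda i: (self.samples[i].day or 0))
        return groups

    def batch_samples(self) -> dict[str, list[int]]:
        groups: dict[str, list[int]] = {}
        for i, s in enumerate(self.samples):
            groups.setdefault(s.batch_id, []).append(i)
        return groups


@dataclass(frozen=True)
class ORF:
    """A (possibly multi-segment) open reading frame.

    Segments are 1-based inclusive ``(start, end)`` pairs in ascending genomic
    order; for minus-strand ORFs the coding sequence runs through the
    reverse complement from the last segment's end back to the first start.
    """

    name: str
    segments: tuple[tuple[int, int], ...]
    strand: str
    frame_ok: bool = True

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        segs = tuple(tuple(seg) for seg in self.segments)
        if not segs:
            raise ValueError(f"ORF {self.name}: needs at least one segment")
        for start, end in segs:
            if start < 1 or end < start:
                raise ValueError(f"ORF {self.name}: bad segment ({start}, {end})")
        for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
            if s2 <= e1:
                raise ValueError(f"ORF {self.name}: segments overlap or unsorted")
        object.__setattr__(self, "segments", segs)
        if self.length % 3 != 0:
            object.__setattr__(self, "frame_ok", False)

    @property
    def start(self) -> int:
        return self.segments[0][0]

    @property
    def end(self) -> int:
        return self.segments[-1][1]

    @property
    def length(self) -> int:
        return sum(end - start + 1 for start, end in self.segments)

    def covers(self, pos: int) -> bool:
        return any(start <= pos <= end for start, end in self.segments)

    def genomic_positions(self) -> list[int]:
        """Genomic positions in coding (5'->3' of the mRNA) order."""
        ascending = [
            p for start, end in self.segments for p in range(start, end + 1)
        ]
        return ascending if self.strand == "+" else ascending[::-1]


@dataclass
class GenomeAnnotation:
    """Contig length, ORF intervals, and optionally the reference sequence."""

    contig: str
    genome_length: int
    orfs: list[ORF] = field(default_factory=list)
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise ValueError("genome_length must be positive")
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if len(self.sequence) != self.genome_length:
                raise ValueError(
                    f"sequence length {len(self.sequence)} != genome_length "
                    f"{self.genome_length}"
                )
        for orf in self.orfs:
            if orf.start < 1 or orf.end > self.genome_length:
                raise ValueError(
                    f"ORF {orf.name} ({orf.start}-{orf.end}) outside "
                    f"[1, {self.genome_length}]"
                )

    def base_at(self, pos: int) -> str:
        if self.sequence is None:
            raise ValueError("annotation has no sequence attached")
        return self.sequence[pos - 1]

    def coding_mask(self) -> np.ndarray:
        """Boolean array of length genome_length: covered by any ORF segment."""
        mask = np.zeros(self.genome_length, dtype=bool)
        for orf in self.orfs:
            for start, end in orf.segments:
                mask[start - 1 : end] = True
        return mask


def new_table(
    sites: Sequence[VariantSite],
    samples: Sequence[SampleMeta],
    ref_counts,
    alt_counts,
    min_depth: int = 10,
) -> VariantTable:
    """Convenience constructor accepting any array-likes."""
    return VariantTable(
        sites=list(sites),
        samples=list(samples),
        ref_counts=np.asarray(ref_counts),
        alt_counts=np.asarray(alt_counts),
        min_depth=min_depth,
    )


__all__ = [
    "BASES",
    "Treatment",
    "SampleMeta",
    "VariantSite",
    "VariantTable",
    "ORF",
    "GenomeAnnotation",
    "new_table",
    "replace",
]
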