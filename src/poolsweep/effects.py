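"""Codon-level SNP effect classification and the exhaustive mutational null.

Each SNP is classified against the reference sequence and ORF annotation
into one of: ``intergenic``, ``synonymous``, ``nonsynonymous``,
``start_lost``, ``stop_gained``, ``stop_lost`` (standard genetic code).
Overlapping ORFs are resolved by severity — start/stop changes outrank
nonsynonymous, which outranks synonymous — with ties broken by the lowest
ORF start so classification is deterministic.

The *null spectrum* enumerates all three alternative bases at every
reference position (3L variants for a genome of length L) and classifies
each one; it is the expected effect distribution under a uniform per-site
mutation probability, against which the observed spectrum is compared with
a Pearson chi-squared statistic and a Monte-Carlo p-value (resampling 2xK
tables with fixed margins).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id
from scipy import stats as sps

from .model import BASES, GenomeAnnotation, ORF, VariantSite

EFFECT_CLASSES = (
    "intergenic",
    "synonymous",
    "nonsynonymous",
    "start_lost",
    "stop_gained",
    "stop_lost",
)

#: start/stop changes > nonsynonymous > synonymous > intergenic
SEVERITY = {
    "intergenic": 0,
    "synonymous": 1,
    "nonsynonymous": 2,
    "start_lost": 3,
    "stop_gained": 3,
    "stop_lost": 3,
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

_TABLE = unambiguous_dna_by_id[1]
#: codon -> amino acid, with '*' for stop (standard code)
CODON_TO_AA = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _classify_codon_change(
    ref_codon: str, alt_codon: str, codon_index: int
) -> str:
    aa_ref = CODON_TO_AA[ref_codon]
    aa_alt = CODON_TO_AA[alt_codon]
    if aa_ref == "*" and aa_alt != "*":
        return "stop_lost"
    if aa_alt == "*" and aa_ref != "*":
        return "stop_gained"
    if codon_index == 0 and ref_codon == "ATG":
        return "start_lost"
    if aa_ref == aa_alt:
        return "synonymous"
    return "nonsynonymous"


def _classify_in_orf(
    genome: GenomeAnnotation, orf: ORF, pos: int, alt_base: str
) -> str:
    """Effect of pos->alt within one frame-correct ORF."""
    positions = orf.genomic_positions()
    cds_index = positions.index(pos)
    codon_index = cds_index // 3
    within = cds_index % 3
    codon_pos = positions[3 * codon_index : 3 * codon_index + 3]
    if orf.strand == "+":
        ref_codon = "".join(genome.base_at(p) for p in codon_pos)
        alt = alt_base
    else:
        ref_codon = "".join(
            genome.base_at(p).translate(_COMPLEMENT) for p in codon_pos
        )
        alt = alt_base.translate(_COMPLEMENT)
    alt_codon = ref_codon[:within] + alt + ref_codon[within + 1 :]
    return _classify_codon_change(ref_codon, alt_codon, codon_index)


def classify_snp(site: VariantSite, genome: GenomeAnnotation) -> str:
    """Classify one SNP; raises if the stated ref base mismatches the
    reference sequence. ORFs flagged out-of-frame are skipped."""
    ref = genome.base_at(site.pos)
    if ref != site.ref_base:
        raise ValueError(
            f"ref mismatch at {site.contig}:{site.pos}: site says "
            f"{site.ref_base}, reference has {ref}"
        )
    best: Optional[str] = None
    for orf in sorted(genome.orfs, key=lambda o: o.start):
        if not orf.frame_ok or not orf.covers(site.pos):
            continue
        cls = _classify_in_orf(genome, orf, site.pos, site.alt_base)
        if best is None or SEVERITY[cls] > SEVERITY[best]:
            best = cls
    return best if best is not None else "intergenic"


@dataclass
class EffectSpectrum:
    """Counts of variants per effect class."""

    counts: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in EFFECT_CLASSES}
    )

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def as_array(self, classes: Sequence[str] = EFFECT_CLASSES) -> np.ndarray:
        return np.array([self.counts.get(c, 0) for c in classes], dtype=np.int64)

    def lumped(self) -> "EffectSpectrum":
        """Merge start/stop classes into one ``start_stop`` bin."""
        out = {
            "intergenic": self.counts.get("intergenic", 0),
            "synonymous": self.counts.get("synonymous", 0),
            "nonsynonymous": self.counts.get("nonsynonymous", 0),
            "start_stop": sum(
                self.counts.get(c, 0)
                for c in ("start_lost", "stop_gained", "stop_lost")
            ),
        }
        return EffectSpectrum(counts=out)

    @classmethod
    def from_classes(cls, classes: Sequence[str]) -> "EffectSpectrum":
        spec = cls()
        for c in classes:
            spec.counts[c] = spec.counts.get(c, 0) + 1
        return spec


def classify_all(genome: GenomeAnnotation) -> np.ndarray:
    """Class codes for every possible SNP: array of shape (L, 3).

    Column order is the three alternative bases in A<C<G<T order with the
    reference base removed. Codes index into :data:`EFFECT_CLASSES`.
    """
    if genome.sequence is None:
        raise ValueError("annotation has no sequence attached")
    L = genome.genome_length
    code_of = {c: k for k, c in enumerate(EFFECT_CLASSES)}
    sev = np.array([SEVERITY[c] for c in EFFECT_CLASSES])
    codes = np.zeros((L, 3), dtype=np.int8)  # 0 = intergenic
    alts_of = {b: [x for x in BASES if x != b] for b in BASES}
    for orf in sorted(genome.orfs, key=lambda o: o.start):
        if not orf.frame_ok:
            continue
        positions = orf.genomic_positions()
        if orf.strand == "+":
            cds = "".join(genome.base_at(p) for p in positions)
        else:
            cds = "".join(
                genome.base_at(p).translate(_COMPLEMENT) for p in positions
            )
        for ci in range(len(cds) // 3):
            ref_codon = cds[3 * ci : 3 * ci + 3]
            for within in range(3):
                gpos = positions[3 * ci + within]
                ref_base = genome.base_at(gpos)
                for col, alt_base in enumerate(alts_of[ref_base]):
                    alt = (
                        alt_base
                        if orf.strand == "+"
                        else alt_base.translate(_COMPLEMENT)
                    )
                    alt_codon = (
                        ref_codon[:within] + alt + ref_codon[within + 1 :]
                    )
                    cls = _classify_codon_change(ref_codon, alt_codon, ci)
                    new = code_of[cls]
                    old = codes[gpos - 1, col]
                    if sev[new] > sev[old]:
                        codes[gpos - 1, col] = new
    return codes


def null_spectrum(genome: GenomeAnnotation) -> EffectSpectrum:
    """Effect spectrum of all 3L possible single-base changes."""
    codes = classify_all(genome)
    counts = np.bincount(codes.ravel(), minlength=len(EFFECT_CLASSES))
    return EffectSpectrum(
        counts={c: int(n) for c, n in zip(EFFECT_CLASSES, counts)}
    )


def empirical_spectrum(
    sites: Sequence[VariantSite], genome: GenomeAnnotation
) -> EffectSpectrum:
    return EffectSpectrum.from_classes(
        [classify_snp(s, genome) for s in sites]
    )


def spectrum_test(
    empirical: EffectSpectrum,
    null: EffectSpectrum,
    n_mc: int = 10000,
    seed: int = 0,
) -> float:
    """Monte-Carlo Pearson chi-squared comparison of two effect spectra.

    The two spectra form a 2xK contingency table (classes empty in both rows
    are dropped). The statistic is Pearson's X^2 against independence;
    the p-value is the add-one Monte-Carlo estimate over tables resampled
    with both margins fixed.
    """
    classes = sorted(
        set(empirical.counts) | set(null.counts),
        key=lambda c: (
            EFFECT_CLASSES.index(c) if c in EFFECT_CLASSES else len(EFFECT_CLASSES)
        ),
    )
    row1 = empirical.as_array(classes)
    row2 = null.as_array(classes)
    keep = (row1 + row2) > 0
    row1, row2 = row1[keep], row2[keep]
    if row1.sum() < 1:
        raise ValueError("empirical spectrum is empty")

    def x2(r1, r2):
        table = np.vstack([r1, r2]).astype(float)
        rowsum = table.sum(axis=1, keepdims=True)
        colsum = table.sum(axis=0, keepdims=True)
        expected = rowsum * colsum / table.sum()
        return float(((table - expected) ** 2 / expected).sum())

    observed = x2(row1, row2)
    rng = np.random.default_rng(seed)
    n1 = int(row1.sum())
    col_totals = (row1 + row2).astype(np.int64)
    hits = 0
    for _ in range(n_mc):
        sim1 = rng.multivariate_hypergeometric(col_totals, n1)
        if x2(sim1, col_totals - sim1) >= observed - 1e-12:
            hits += 1
    return (1 + hits) / (n_mc + 1)


def intergenic_fraction(genome: GenomeAnnotation) -> float:
    """Fraction of reference positions covered by no ORF segment."""
    return float(1.0 - genome.coding_mask().mean())


__all__ = [
    "EFFECT_CLASSES",
    "SEVERITY",
    "CODON_TO_AA",
    "revcomp",
    "classify_snp",
    "classify_all",
    "null_spectrum",
    "empirical_spectrum",
    "EffectSpectrum",
    "spectrum_test",
    "intergenic_fraction",
]
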