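"""Codon effect classification, the exhaustive null, spectrum comparison."""

import numpy as np
import pytest
from hypothesis import given, strategies as hst

from poolsweep import effects as fx
from poolsweep.model import GenomeAnnotation, ORF, VariantSite
from poolsweep.simulate import make_toy_genome, random_orf_spec

from oracles import classify_by_translation


def snp(pos, ref, alt):
    return VariantSite("toy1", pos, ref, alt)


class TestClassifySnp:
    def test_standard_code_classes(self, toy_genome):
        # ATG AAA TAA
        assert fx.classify_snp(snp(6, "A", "G"), toy_genome) == "synonymous"
        assert fx.classify_snp(snp(5, "A", "G"), toy_genome) == "nonsynonymous"
        assert fx.classify_snp(snp(4, "A", "T"), toy_genome) == "stop_gained"
        assert fx.classify_snp(snp(7, "T", "C"), toy_genome) == "stop_lost"
        assert fx.classify_snp(snp(1, "A", "G"), toy_genome) == "start_lost"

    def test_minus_strand_mirrors_plus_strand(self, toy_genome_minus):
        # TTATTTCAT with ORF 1-9 '-': CDS is ATG AAA TAA again; pos 4 T->C
        # on the plus strand is CDS pos 6 A->G, a synonymous Lys change
        assert fx.classify_snp(snp(4, "T", "C"), toy_genome_minus) == "synonymous"
        assert fx.classify_snp(snp(9, "T", "C"), toy_genome_minus) == "start_lost"

    def test_intergenic_when_no_orf_covers(self):
        genome = GenomeAnnotation(
            contig="c", genome_length=12, orfs=[ORF("o", ((1, 9),), "+")],
            sequence="ATGAAATAACCC",
        )
        assert fx.classify_snp(snp(11, "C", "T"), genome) == "intergenic"

    def test_ref_mismatch_is_hard_error(self, toy_genome):
        with pytest.raises(ValueError, match="ref mismatch"):
            fx.classify_snp(snp(1, "C", "G"), toy_genome)

    def test_out_of_frame_orf_skipped(self):
        genome = GenomeAnnotation(
            contig="c", genome_length=10, orfs=[ORF("o", ((1, 10),), "+")],
            sequence="ATGAAATAAC",
        )
        assert fx.classify_snp(snp(5, "A", "G"), genome) == "intergenic"

    def test_overlap_resolved_by_severity(self):
        # two overlapping plus-strand reading frames over one sequence; the
        # reported class must carry the maximum severity over covering ORFs
        genome = GenomeAnnotation(
            contig="toy1",
            genome_length=18,
            orfs=[ORF("o1", ((1, 12),), "+"), ORF("o2", ((7, 18),), "+")],
            sequence="ATGAAATGTTAACCCTAA",
        )
        for pos in range(1, 19):
            ref = genome.base_at(pos)
            for alt in "ACGT":
                if alt == ref:
                    continue
                per_orf = [
                    classify_by_translation(genome, orf, pos, alt)
                    for orf in genome.orfs
                    if orf.covers(pos)
                ]
                got = fx.classify_snp(snp(pos, ref, alt), genome)
                assert fx.SEVERITY[got] == max(fx.SEVERITY[c] for c in per_orf)


class TestClassifierAgainstTranslationOracle:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_exhaustive_on_random_toy_genomes(self, seed):
        spec = random_orf_spec(400, 3, seed=seed, min_codons=8, max_codons=30)
        genome = make_toy_genome(400, spec, seed=seed)
        by_start = sorted(genome.orfs, key=lambda o: o.start)
        for pos in range(1, 401):
            ref = genome.base_at(pos)
            covering = [o for o in by_start if o.covers(pos)]
            for alt in "ACGT":
                if alt == ref:
                    continue
                got = fx.classify_snp(snp(pos, ref, alt), genome)
                if not covering:
                    assert got == "intergenic"
                else:
                    (orf,) = covering  # specs are non-overlapping
                    assert got == classify_by_translation(genome, orf, pos, alt)

    def test_multisegment_minus_strand_orf(self):
        genome = make_toy_genome(50, [], seed=0)
        orf = ORF("split", ((5, 13), (20, 28)), "-")
        # build a valid CDS by hand on the minus strand: revcomp segments
        seq = list(genome.sequence)
        cds = "ATGGCCAAATTTCCCTAA"  # 18 bases
        positions = orf.genomic_positions()
        comp = str.maketrans("ACGT", "TGCA")
        for base, pos in zip(cds, positions):
            seq[pos - 1] = base.translate(comp)
        genome = GenomeAnnotation(
            contig="c", genome_length=50, orfs=[orf], sequence="".join(seq)
        )
        for pos in [p for s, e in orf.segments for p in range(s, e + 1)]:
            ref = genome.base_at(pos)
            for alt in "ACGT":
                if alt == ref:
                    continue
                got = fx.classify_snp(snp(pos, ref, alt), genome)
                assert got == classify_by_translation(genome, orf, pos, alt)


class TestStrandSymmetry:
    @given(seed=hst.integers(0, 50))
    def test_classification_invariant_under_reverse_complement(self, seed):
        L = 120
        spec = random_orf_spec(L, 2, seed=seed, min_codons=6, max_codons=15)
        genome = make_toy_genome(L, spec, seed=seed)
        flipped = GenomeAnnotation(
            contig=genome.contig,
            genome_length=L,
            orfs=[
                ORF(
                    o.name,
                    tuple(
                        sorted((L - e + 1, L - s + 1) for s, e in o.segments)
                    ),
                    "-" if o.strand == "+" else "+",
                )
                for o in genome.orfs
            ],
            sequence=fx.revcomp(genome.sequence),
        )
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rng = np.random.default_rng(seed)
        for _ in range(25):
            pos = int(rng.integers(1, L + 1))
            ref = genome.base_at(pos)
            alt = rng.choice([b for b in "ACGT" if b != ref])
            mirrored = VariantSite(
                genome.contig, L - pos + 1, comp[ref], comp[alt]
            )
            assert fx.classify_snp(snp(pos, ref, alt), genome) == fx.classify_snp(
                mirrored, flipped
            )


class TestNullSpectrum:
    def test_toy_genome_exhaustive_enumeration(self, toy_genome):
        # hand enumeration over all 27 possible changes of ATG AAA TAA
        spec = fx.null_spectrum(toy_genome)
        assert spec.total == 27
        by_hand = {c: 0 for c in fx.EFFECT_CLASSES}
        for pos in range(1, 10):
            ref = toy_genome.base_at(pos)
            for alt in "ACGT":
                if alt != ref:
                    by_hand[fx.classify_snp(snp(pos, ref, alt), toy_genome)] += 1
        assert spec.counts == by_hand

    def test_no_orfs_all_intergenic(self):
        genome = make_toy_genome(30, [], seed=1)
        spec = fx.null_spectrum(genome)
        assert spec.counts["intergenic"] == spec.total == 90

    @given(seed=hst.integers(0, 30))
    def test_total_is_three_l_for_any_annotation(self, seed):
        L = 150
        spec_orfs = random_orf_spec(L, 2, seed=seed, min_codons=5, max_codons=12)
        genome = make_toy_genome(L, spec_orfs, seed=seed)
        assert fx.null_spectrum(genome).total == 3 * L

    def test_matches_per_site_classifier(self):
        genome = make_toy_genome(
            200, random_orf_spec(200, 3, seed=9, min_codons=6, max_codons=15), seed=9
        )
        codes = fx.classify_all(genome)
        alts_of = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}
        for pos in range(1, 201):
            ref = genome.base_at(pos)
            for col, alt in enumerate(alts_of[ref]):
                expected = fx.classify_snp(snp(pos, ref, alt), genome)
                assert fx.EFFECT_CLASSES[codes[pos - 1, col]] == expected


class TestSpectrumTest:
    def test_proportional_spectra_give_p_one(self):
        emp = fx.EffectSpectrum(counts={"a": 10, "b": 30})
        null = fx.EffectSpectrum(counts={"a": 100, "b": 300})
        assert fx.spectrum_test(emp, null, n_mc=500, seed=1) == 1.0

    def test_extreme_difference_detected(self):
        from oracles import hypergeom_pmf_exact

        emp = fx.EffectSpectrum(counts={"a": 100, "b": 0})
        null = fx.EffectSpectrum(counts={"a": 50, "b": 50})
        p = fx.spectrum_test(emp, null, n_mc=10000, seed=2)
        assert p <= 0.001
        # exact tail (the two extreme tables for these margins) is far below
        # the Monte-Carlo floor; the add-one estimate must stay above it
        exact = hypergeom_pmf_exact(100, 200, 100, 150) + hypergeom_pmf_exact(
            50, 200, 100, 150
        )
        assert exact < p

    def test_monte_carlo_p_matches_exact_tail_on_2x2(self):
        """Dual route: the MC p agrees with exact hypergeometric summation."""
        from oracles import hypergeom_pmf_exact

        emp = fx.EffectSpectrum(counts={"a": 30, "b": 70})
        null = fx.EffectSpectrum(counts={"a": 50, "b": 50})
        p = fx.spectrum_test(emp, null, n_mc=20000, seed=4)

        def x2_of(k):
            # table [[k, 100-k], [80-k, 20+k]] with margins fixed
            table = np.array([[k, 100 - k], [80 - k, 20 + k]], dtype=float)
            rowsum = table.sum(axis=1, keepdims=True)
            colsum = table.sum(axis=0, keepdims=True)
            expected = rowsum * colsum / 200
            return ((table - expected) ** 2 / expected).sum()

        obs = x2_of(30)
        exact = sum(
            hypergeom_pmf_exact(k, 200, 80, 100)
            for k in range(0, 81)
            if x2_of(k) >= obs - 1e-12
        )
        se = np.sqrt(exact * (1 - exact) / 20000)
        assert p == pytest.approx(exact, abs=3 * se + 1e-4)

    def test_seed_determinism(self):
        emp = fx.EffectSpectrum(counts={"a": 20, "b": 10, "c": 5})
        null = fx.EffectSpectrum(counts={"a": 300, "b": 200, "c": 100})
        p1 = fx.spectrum_test(emp, null, n_mc=2000, seed=7)
        p2 = fx.spectrum_test(emp, null, n_mc=2000, seed=7)
        assert p1 == p2

    def test_empty_class_dropped(self):
        emp = fx.EffectSpectrum(counts={"a": 10, "b": 20, "c": 0})
        null = fx.EffectSpectrum(counts={"a": 100, "b": 200, "c": 0})
        assert fx.spectrum_test(emp, null, n_mc=200, seed=3) == 1.0

    def test_lumped_bins(self):
        spec = fx.EffectSpectrum(
            counts={
                "intergenic": 1,
                "synonymous": 2,
                "nonsynonymous": 3,
                "start_lost": 1,
                "stop_gained": 2,
                "stop_lost": 3,
            }
        )
        assert spec.lumped().counts["start_stop"] == 6
        assert spec.lumped().total == spec.total


class TestIntergenicFraction:
    def test_limits(self):
        none = make_toy_genome(30, [], seed=2)
        assert fx.intergenic_fraction(none) == 1.0
        full = make_toy_genome(30, [(1, 30, "+")], seed=2)
        assert fx.intergenic_fraction(full) == 0.0

    def test_partial_coverage(self):
        genome = make_toy_genome(60, [(1, 57, "+")], seed=3)
        assert fx.intergenic_fraction(genome) == pytest.approx(0.05)
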