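"""Classify SNP effects on a toy genome and compare the observed spectrum
with the exhaustive all-possible-mutations null.

The null spectrum enumerates all 3L single-base changes of the reference
and classifies each; a Monte-Carlo Pearson chi-squared test then asks
whether the observed class distribution departs from that expectation.
"""

from poolsweep import effects as fx
from poolsweep.model import VariantSite
from poolsweep.simulate import make_toy_genome, random_orf_spec

genome = make_toy_genome(3000, random_orf_spec(3000, 8, seed=5), seed=5)
print(f"toy genome: {genome.genome_length} bp, {len(genome.orfs)} ORFs, "
      f"intergenic fraction {fx.intergenic_fraction(genome):.2f}")

null = fx.null_spectrum(genome)
print("null spectrum (all", null.total, "possible changes):", null.counts)

# pretend the first coding positions of each ORF were hit by mutations
sites = []
for orf in genome.orfs[:5]:
    pos = orf.start + 4
    ref = genome.base_at(pos)
    alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
    sites.append(VariantSite(genome.contig, pos, ref, alt))
emp = fx.empirical_spectrum(sites, genome)
print("observed spectrum:", {k: v for k, v in emp.counts.items() if v})

p = fx.spectrum_test(emp.lumped(), null.lumped(), n_mc=10_000, seed=0)
print(f"Monte-Carlo chi-squared p = {p:.3f} "
      "(small p would mean the observed effects are not a uniform draw)")
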