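"""Scan ORFs for an excess of variable sites, using the published per-gene
counts of the PBCV-1 coevolution experiment as input.

For each of the 812 ORFs a Fisher enrichment test compares its variable-site
count with a uniform scatter of the 67 genome-wide sites over 330,611 bp;
Holm's step-down correction controls the family-wise error rate.
"""

from poolsweep import enrichment as enr
from poolsweep import pbcv1

scan = enr.enrichment_from_counts(
    pbcv1.enrichment_inputs(),
    L_G=pbcv1.GENOME_LENGTH,
    m_total=pbcv1.N_UNIQUE_SNPS,
    alpha=0.05,
)
hits = scan[scan["significant"]]
print(f"{int(scan['significant'].sum())} of {len(scan)} ORFs enriched at "
      "FWER 0.05:")
print(hits[["orf", "length", "m_orf", "p_raw", "p_holm"]].to_string(index=False))

near = enr.neighbor_counts(
    [62145 + 10 * i for i in range(14)] + [259_000, 259_400], window=500
)
print("\nSNP clustering (neighbors within 500 bp incl. the focal site):")
print(near.to_string(index=False))
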