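import numpy as np
import pytest
from hypothesis import settings

from poolsweep.model import (
    GenomeAnnotation,
    ORF,
    SampleMeta,
    Treatment,
    VariantSite,
    VariantTable,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("ci")


def make_samples(
    n_replicates=2, days=(12, 64), batches=None, treatment="weak_demography"
):
    """Sample sheet for n replicates sequenced at the given days."""
    samples = []
    for r in range(n_replicates):
        rep = f"R{r + 1}"
        batch = (
            batches[r]
            if batches is not None
            else ("batchA" if r < (n_replicates + 1) // 2 else "batchB")
        )
        for d in days:
            samples.append(
                SampleMeta(
                    sample_id=f"{rep}_d{d}",
                    replicate_id=rep,
                    treatment=Treatment(treatment),
                    day=d,
                    batch_id=batch,
                )
            )
    return samples


def table_from_counts(alt, depth, samples, quals=None, min_depth=10, pos0=100):
    """Build a VariantTable from alt-count and depth matrices."""
    alt = np.asarray(alt, dtype=np.int64)
    depth = np.asarray(depth, dtype=np.int64)
    n_sites = alt.shape[0]
    quals = quals if quals is not None else [1000.0] * n_sites
    sites = [
        VariantSite("chr1", pos0 + 10 * i, "A", "C", qual=quals[i])
        for i in range(n_sites)
    ]
    return VariantTable(
        sites=sites,
        samples=list(samples),
        ref_counts=depth - alt,
        alt_counts=alt,
        min_depth=min_depth,
    )


@pytest.fixture
def toy_genome():
    """9-bp fully coding genome ATG AAA TAA on the plus strand."""
    return GenomeAnnotation(
        contig="toy1",
        genome_length=9,
        orfs=[ORF(name="orf1", segments=((1, 9),), strand="+")],
        sequence="ATGAAATAA",
    )


@pytest.fixture
def toy_genome_minus():
    """Reverse-complement of the toy genome with a minus-strand ORF."""
    return GenomeAnnotation(
        contig="toy1",
        genome_length=9,
        orfs=[ORF(name="orf1", segments=((1, 9),), strand="-")],
        sequence="TTATTTCAT",
    )
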