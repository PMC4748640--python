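import numpy as np
import pytest

from famhotspot import (
    CohortSpec,
    FamilySpec,
    MutationClass,
    MutationRecord,
    ProteinRecord,
    generate_cohort,
    generate_family,
)


@pytest.fixture
def small_family():
    """Three short, closely related sequences."""
    return [
        ProteinRecord("GENEA", "PA", "MKTAYIAKQRQISFVKSHFSRQ"),
        ProteinRecord("GENEB", "PB", "MKTAYIAKQRQISFVKSHFSRQ"),
        ProteinRecord("GENEC", "PC", "MKTAYLAKQRQISFVKAHFSRQ"),
    ]


@pytest.fixture
def synthetic_family():
    records, true_aln = generate_family(FamilySpec(n_members=8, length=120, seed=42))
    return records, true_aln


@pytest.fixture
def planted_cohort(synthetic_family):
    records, true_aln = synthetic_family
    spec = CohortSpec(
        n_samples=40,
        background_rate=1.0,
        hotspot_columns=((30, 0.3),),
        seed=7,
    )
    muts, truth = generate_cohort(spec, records, true_aln)
    return muts, truth


def make_mutation(gene="GENEA", sample="S1", tumor="brca", mclass=MutationClass.MISSENSE,
                  ref="M", pos=1, alt="V"):
    return MutationRecord(gene, sample, tumor, mclass, ref, pos, alt)
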