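import pandas as pd
import pytest
from hypothesis import settings

from famprio.cohort_io import (
    AnnotationBundle,
    Family,
    FamilyCohort,
    Member,
    VariantRecord,
    parse_variant_key,
)
from famprio.predictors import PREDICTORS
from famprio.prioritization import Thresholds

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_record(
    key="1_1000000_A_G",
    gene="GENE1",
    consequence="missense_variant",
    canonical=True,
    cadd=30.0,
    afs=(None, None, None),
    calls=None,
    gerp=3.0,
    phastcons=0.5,
    phylop=4.0,
    genotypes=None,
    **extra,
):
    """Hand-built record clearing every default threshold unless told not to."""
    predictor_calls = {p: "deleterious" for p in PREDICTORS}
    if calls is not None:
        predictor_calls.update(calls)
    ann = AnnotationBundle(
        af_overall=afs[0],
        af_nfe=afs[1],
        af_popmax=afs[2],
        cadd_phred=cadd,
        predictor_calls=predictor_calls,
        gerp=gerp,
        phastcons=phastcons,
        phylop=phylop,
        consequence=consequence,
        canonical=canonical,
        **extra,
    )
    return VariantRecord(
        key=parse_variant_key(key),
        gene=gene,
        annotations=ann,
        genotypes=genotypes or {},
    )


def make_cohort(families):
    """families: {fam_id: [(sample, affected, sequenced), ...]}"""
    fams = {}
    for fam_id, members in families.items():
        fams[fam_id] = Family(
            family_id=fam_id,
            members=[
                Member(
                    sample_id=s,
                    family_id=fam_id,
                    father=None,
                    mother=None,
                    sex=None,
                    affected=aff,
                    sequenced=seq,
                )
                for s, aff, seq in members
            ],
        )
    return FamilyCohort(families=fams)


@pytest.fixture
def thresholds():
    return Thresholds()


@pytest.fixture
def two_case_cohort():
    return make_cohort(
        {
            "F1": [("A1", True, True), ("A2", True, True), ("U1", False, False)],
            "Mx1": [("P1", True, True), ("R1", False, False)],
        }
    )


@pytest.fixture
def edge_tsv(tmp_path):
    df = pd.DataFrame(
        {
            "protein_a": ["X", "Y", "Y", "Z"],
            "protein_b": ["Y", "X", "Z", "Z"],
            "experiments": [0.9, 0.7, 0.5, 0.8],
            "databases": [0.0, 0.4, 0.0, 0.1],
            "coexpression": [0.2, 0.0, 0.3, 0.0],
        }
    )
    path = tmp_path / "edges.tsv"
    df.to_csv(path, sep="\t", index=False)
    return path
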