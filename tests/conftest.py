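import numpy as np
import pandas as pd
import pytest

from apohot.io_formats import CohortTable, SnvRecord, load_packaged_signature_reference
from apohot.synthetic_data import default_config, simulate_all


def make_record(
    sample,
    pos,
    ref="C",
    alt="T",
    gene="GENE",
    chrom="chr1",
    context25=None,
    clonality=None,
    patient=None,
    protein_change=None,
):
    """Hand-rolled SNV record with a consistent default context."""
    if context25 is None:
        context25 = "A" * 11 + "T" + ref + "A" * 12
    return SnvRecord(
        patient_id=patient or sample,
        sample_id=sample,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        protein_change=protein_change,
        context25=context25,
        clonality=clonality,
    )


@pytest.fixture(scope="session")
def sig_reference():
    return load_packaged_signature_reference()


@pytest.fixture(scope="session")
def sim():
    """One default synthetic study shared across tests (seed fixed)."""
    return simulate_all(default_config(seed=7))


@pytest.fixture()
def tiny_cohort():
    records = [
        make_record("s1", 100, patient="p1"),
        make_record("s2", 100, patient="p2"),
        make_record("s2", 200, patient="p2", ref="G", alt="A",
                    context25="A" * 12 + "G" + "A" * 12),
    ]
    return CohortTable(records=records)
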