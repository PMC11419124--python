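import io

import pandas as pd
import pytest

from affinity_forge.curation import ActivityRecord
from affinity_forge.fixtures import FixtureSpec, generate_curation_fixture
from affinity_forge.ingest import read_activity_records


def record(
    rid="R1",
    uniprot="P00519",
    target="CHEMBL1862",
    smiles="CCO",
    rtype="Ki",
    value=1.0,
    units="nM",
    doc="DOC1",
    year=2010,
    authors=("Adler A",),
    index=0,
    mtype=None,
    pvalue=None,
):
    """Shorthand ActivityRecord factory for stage-level tests."""
    return ActivityRecord(
        record_id=rid,
        uniprot_id=uniprot,
        target_id=target,
        smiles=smiles,
        rtype=rtype,
        value=value,
        units=units,
        document_id=doc,
        year=year,
        authors=tuple(authors),
        index=index,
        mtype=mtype,
        pvalue=pvalue,
    )


@pytest.fixture
def make_record():
    return record


def records_from_frame(frame: pd.DataFrame):
    """Round a fixture table through CSV, as the cascade would ingest it."""
    return read_activity_records(io.StringIO(frame.to_csv(index=False)))


@pytest.fixture
def curation_fixture():
    spec = FixtureSpec(n_records=200, seed=1)
    frame, truth = generate_curation_fixture(spec)
    return spec, frame, truth
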