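import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `helpers`

from metarepo import fixtures, storage
from metarepo.metamodel import (
    AttributeDef,
    LoopDef,
    MetadataGroup,
    SchemaHeader,
    define_datatype,
)


@pytest.fixture()
def store():
    return storage.Store()


@pytest.fixture()
def bootstrapped_store():
    st = storage.Store()
    fixtures.bootstrap_datatypes(st)
    return st


@pytest.fixture(scope="session")
def cohort_store(tmp_path_factory):
    """The seeded 20-subject study cohort (shared, read-only in tests)."""
    st = storage.Store()
    fixtures.bootstrap_datatypes(st)
    report = fixtures.generate_cohort(
        st,
        fixtures.CohortSpec(n_subjects=20, seed=42),
        image_dir=tmp_path_factory.mktemp("dicom20"),
    )
    st.cohort_report = report
    return st


@pytest.fixture(scope="session")
def large_cohort_store(tmp_path_factory):
    """A 200-subject store for the query-oracle equivalence sweep."""
    st = storage.Store()
    fixtures.bootstrap_datatypes(st)
    fixtures.generate_cohort(
        st,
        fixtures.CohortSpec(n_subjects=200, seed=7),
        image_dir=tmp_path_factory.mktemp("dicom200"),
    )
    return st


@pytest.fixture()
def mri_schema():
    return define_datatype(
        SchemaHeader(
            datatype_name="MRI",
            description="structural scan",
            file_associated=True,
            created_at="2012-01-01T00:00:00",
        ),
        [
            MetadataGroup(
                "acquisition",
                (
                    AttributeDef("field_strength", "decimal", required=True),
                    AttributeDef("sequence", "text", required=True),
                ),
            )
        ],
    )


@pytest.fixture()
def reagent_schema():
    """A loop-bearing type: description/concentration/amount per reagent."""
    return define_datatype(
        SchemaHeader(datatype_name="Microarray Assay",
                     created_at="2012-01-01T00:00:00"),
        [
            MetadataGroup(
                "protocol",
                (
                    AttributeDef("platform", "text"),
                    LoopDef(
                        "reagent",
                        (
                            AttributeDef("description", "text", required=True),
                            AttributeDef("concentration", "decimal",
                                         required=True),
                            AttributeDef("amount", "decimal", required=True),
                        ),
                    ),
                ),
            )
        ],
    )
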