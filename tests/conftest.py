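import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from omrlap.annotations import AnnotationRecord
from omrlap.synthetic import SyntheticSpec
from omrlap.terminology import TerminologyGraph

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_record(**kwargs) -> AnnotationRecord:
    defaults = dict(
        patient_id="0000",
        document_id="doc-1",
        corpus_tag="CN",
        note_date=dt.date(2016, 3, 10),
        section="Diagnosis",
        term="chest xray",
        cui=None,
        semantic_group="PROC",
        experiencer="Patient",
        assertion="present",
    )
    defaults.update(kwargs)
    return AnnotationRecord(**defaults)


@pytest.fixture
def small_spec() -> SyntheticSpec:
    """A deliberately small planted corpus exercising every region."""
    return SyntheticSpec(
        seed=11,
        n_patients=10,
        region_cardinalities={"A": 8, "B": 12, "C": 6, "D": 5, "E": 15, "F": 10, "G": 30},
        region_group_counts=None,
        region_score_sums=None,
        n_specialty_exclusive=4,
    )


@pytest.fixture
def toy_graph() -> TerminologyGraph:
    """heart -- aorta -- valve chain plus a synonym pair and an island.

    C1(heart) is parent of C2(aorta); C2 is parent of C3(valve); C4 is an
    isolated concept; "structure of heart" and "cardiac" both map to C1.
    """
    g = TerminologyGraph()
    g.add_concept("C1", "heart")
    g.add_concept("C2", "aorta")
    g.add_concept("C3", "valve")
    g.add_concept("C4", "anxiety")
    g.add_edge("C2", "C1")
    g.add_edge("C3", "C2")
    g.add_term("structure of heart", "C1")
    g.add_term("cardiac", "C1")
    return g
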