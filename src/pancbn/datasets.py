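"""Small packaged synthetic fixtures for examples and quick tests.

Both files are synthetic: the study table is a 12-study x 6-variable draw
from :func:`pancbn.synthetic.simulate_study_table`, and the cohort is 40
patients forward-sampled from the shipped default post-operative network
(20% missingness, 80% resection rate).  Neither contains real patient or
study data.
"""

from __future__ import annotations

from importlib.resources import files

from .evidence import StudyTable
from .prediction import PatientRecord, read_cohort


def _data_path(name: str):
    return files("pancbn.data").joinpath(name)


def load_example_study_table() -> StudyTable:
    """The committed 12-study, 6-variable synthetic extraction table."""
    import io

    import pandas as pd

    text = _data_path("synthetic_studies_small.csv").read_text()
    return StudyTable.from_frame(pd.read_csv(io.StringIO(text), comment="#"))


def load_example_cohort() -> list[PatientRecord]:
    """The committed 40-patient synthetic cohort (default-network states)."""
    import io

    text = _data_path("synthetic_cohort_small.csv").read_text()
    return read_cohort(io.StringIO(text))
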