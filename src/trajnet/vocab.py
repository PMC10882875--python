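"""Canonical disease vocabulary.

Fourteen chronic-disease codes used throughout the pipeline. The table is
shipped as CSV so external tools can consume it; :data:`DISEASES` is the
canonical in-process ordering.
"""

from importlib import resources

import pandas as pd

DISEASES: tuple[str, ...] = (
    "hypertension",
    "dyslipidemia",
    "diabetes",
    "cancer",
    "chronic_lung",
    "liver",
    "heart",
    "stroke",
    "kidney",
    "digestive",
    "emp",
    "mrd",
    "arthritis",
    "asthma",
)

SURVEY_WAVES: tuple[int, ...] = (2011, 2013, 2015, 2018)


def load_vocabulary() -> pd.DataFrame:
    """Return the packaged disease table (columns ``code``, ``label``)."""
    with resources.files("trajnet.data").joinpath("diseases.csv").open() as fh:
        return pd.read_csv(fh)
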