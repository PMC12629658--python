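import numpy as np
import pytest

from pufatrace import CellSummary, FameMeasurement, Treatment, parse_fatty_acid


@pytest.fixture
def study_cells():
    """The four (species × pathway) total-CE summaries of the two-species
    swallow/martin study: mean, sample SD, n = 3 per cell."""
    return [
        CellSummary("barn_swallow", "omega3", 75.77, 12.52, 3),
        CellSummary("barn_swallow", "omega6", 46.05, 17.10, 3),
        CellSummary("purple_martin", "omega3", 87.62, 4.32, 3),
        CellSummary("purple_martin", "omega6", 44.42, 6.82, 3),
    ]


def make_measurement(
    bird_id="b1",
    species="barn_swallow",
    treatment=Treatment.LABELLED_ALA,
    fatty_acid="18:3n-3",
    delta13c=-30.0,
    pct_fame=1.0,
):
    return FameMeasurement(
        bird_id, species, treatment, parse_fatty_acid(fatty_acid), delta13c, pct_fame
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20220513)
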