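import warnings

import pytest

from docktriage.datasets import load_panel_annotations, load_selected_descriptors
from docktriage.scoring import RankedCompound

# Published order of the top ten compounds under the score1 scheme
# (ranked ascending by weighted binding-energy score).
SCORE1_TOP10 = (
    "Rutaecarpine",
    "Sesamolin",
    "Corilagin",
    "Apigetrin",
    "Gamabufotalin",
    "Protopine",
    "5-methoxyflavone",
    "7,3',4'-trihydroxyisoflavone",
    "Viaminate",
    "KAN0438757",
)

FINAL_FIVE = (
    "Corilagin",
    "Apigetrin",
    "Protopine",
    "5-methoxyflavone",
    "7,3',4'-trihydroxyisoflavone",
)


@pytest.fixture(scope="session")
def selected_descriptors():
    return load_selected_descriptors()


@pytest.fixture(scope="session")
def panel_annotations():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # shared-CID warning is expected
        return load_panel_annotations()


@pytest.fixture(scope="session")
def published_top10_ranking():
    """The printed top-10 as a ranked list (scores stand in for the real sums)."""
    return [
        RankedCompound(compound_id=cid, score=float(i), rank=i)
        for i, cid in enumerate(SCORE1_TOP10, start=1)
    ]
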