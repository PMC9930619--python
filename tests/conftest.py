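import numpy as np
import pandas as pd
import pytest

from plscog import ParcellationSpec


@pytest.fixture(scope="session")
def dk82():
    return ParcellationSpec.desikan_killiany_82()


@pytest.fixture
def toy_parcellation():
    """Five regions across three lobes: F1, F2 frontal; P1 parietal; T1 temporal; O1 occipital."""
    return ParcellationSpec(
        pd.DataFrame(
            {
                "label": ["F1", "F2", "P1", "T1", "O1"],
                "hemisphere": ["left", "left", "left", "right", "right"],
                "lobe": ["frontal", "frontal", "parietal", "temporal", "occipital"],
            }
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
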