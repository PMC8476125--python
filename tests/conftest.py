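import warnings

import numpy as np
import pytest

from replaystate.pipeline import fit_simulated_encoder
from replaystate.simulate import PlaceFieldBank
from replaystate.track import linear_track, make_grid_1d

warnings.filterwarnings("ignore", message=".*did not converge.*")


@pytest.fixture(scope="session")
def bank() -> PlaceFieldBank:
    """The default 19-cell Gaussian place-field bank on a 180 cm track."""
    return PlaceFieldBank()


@pytest.fixture(scope="session")
def grid60():
    """3 cm grid on the 180 cm linear track (60 bins)."""
    return make_grid_1d(linear_track(180.0), 3.0)


@pytest.fixture(scope="session")
def sim_encoder(bank):
    """One fitted sorted-spike encoder on simulated traversals (seed 0).

    Session-scoped: the fit is the most expensive shared setup step.
    """
    encoder, grid, bank_ = fit_simulated_encoder(bank, seed=0)
    return encoder, grid, bank_
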