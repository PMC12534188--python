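import numpy as np
import pandas as pd
import pytest

from resiglyco.io_formats import make_localizations


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def gaussian_blob(
    centre: tuple[float, float],
    n: int,
    sigma: float,
    rng: np.random.Generator,
    n_frames: int = 40000,
    channel: int = 0,
    precision: float = 3.0,
) -> pd.DataFrame:
    """Localization table for one binding site: n Gaussian draws, random frames."""
    xy = np.asarray(centre, dtype=float) + rng.normal(0.0, sigma, size=(n, 2))
    frames = np.sort(rng.integers(0, n_frames, size=n))
    return make_localizations(
        frames, xy[:, 0], xy[:, 1], np.full(n, precision), channel=channel
    )


def random_table(rng: np.random.Generator, n: int = 50, fov: float = 1000.0) -> pd.DataFrame:
    return make_localizations(
        rng.integers(0, 40000, size=n),
        rng.uniform(0, fov, size=n),
        rng.uniform(0, fov, size=n),
        rng.uniform(1.0, 5.0, size=n),
        photons=rng.uniform(100, 5000, size=n),
        channel=rng.integers(0, 6, size=n),
    )
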