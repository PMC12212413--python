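import numpy as np
import pytest

from petmr_habitats import DwiSeries, Grid, ImageVolume, RoiMask


@pytest.fixture
def grid() -> Grid:
    return Grid((6, 5, 4), (2.0, 2.0, 2.0))


def make_series(adc_true, bvalues=(50.0, 500.0, 800.0), s0=1000.0, grid=None):
    """Noiseless mono-exponential DWI series from a planted ADC field (1e-3 mm^2/s)."""
    adc_true = np.asarray(adc_true, dtype=float)
    if grid is None:
        grid = Grid(adc_true.shape, (2.0, 2.0, 2.0))
    vols = [
        ImageVolume(s0 * np.exp(-b * adc_true / 1e3), grid, f"DWI_b{b:g}") for b in bvalues
    ]
    return DwiSeries(np.asarray(bvalues), vols)


def flat_mask(n: int, name: str = "lesion") -> RoiMask:
    """A 1 x 1 x n line mask covering the whole grid (handy for voxel-list tests)."""
    g = Grid((1, 1, n), (1.0, 1.0, 1.0))
    return RoiMask(np.ones((1, 1, n), dtype=bool), g, name)


def line_volume(values, modality: str = "SUV") -> ImageVolume:
    vals = np.asarray(values, dtype=float).reshape(1, 1, -1)
    g = Grid(vals.shape, (1.0, 1.0, 1.0))
    return ImageVolume(vals, g, modality)
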