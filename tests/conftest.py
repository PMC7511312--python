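import numpy as np
import pytest

from nspef import electro, imaging, synthetic


@pytest.fixture
def haem_cell():
    """Reference cell: a = 14 um, C_m = 1 uF/cm^2, sigma_i = 10, sigma_e = 1.6 mS/cm."""
    return electro.HAEMATOCOCCUS_CELL


@pytest.fixture
def presets():
    return synthetic.preset_scenarios()


FIELD = 4e6  # 40 kV/cm in V/m


def segment_and_match(img, truth, **segment_kwargs):
    """Segment a synthetic micrograph and pair each region with the nearest
    planted cell. Returns a list of (region, truth_cell) pairs."""
    regions = imaging.segment_cells(img, **segment_kwargs)
    pairs = []
    for region in regions:
        cy, cx = region.centroid
        cell = min(truth.cells, key=lambda c: (c["y"] - cy) ** 2 + (c["x"] - cx) ** 2)
        pairs.append((region, cell))
    return pairs


def brute_force_integrated_density(img_inverted, coords):
    """Independent per-pixel accumulation of (G_inv - R_inv) over a region."""
    total = 0
    for row, col in coords:
        total += int(img_inverted[row, col, 1]) - int(img_inverted[row, col, 0])
    return total
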