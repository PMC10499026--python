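import numpy as np
import pytest

from planarpol.synthetic import (PatternSpec, gen_cell_tessellation,
                                 gen_follicle_positions,
                                 gen_orientation_pattern,
                                 paint_junction_intensity)


@pytest.fixture(scope="session")
def tessellation_500():
    """500-cell jittered Voronoi tessellation shared by polarity tests."""
    return gen_cell_tessellation(500, (700, 700), seed=2)


@pytest.fixture(scope="session")
def painted_40deg(tessellation_500):
    """Tessellation painted with a uniform 40 degree director at moderate
    noise (junction polarity round-trip fixture)."""
    return paint_junction_intensity(tessellation_500, lambda x, y: 40.0,
                                    strength=0.8, noise_sd=0.05, seed=3)


@pytest.fixture(scope="session")
def reversed_patch_field():
    """Ground-truth reversed-patch follicle field (positions + records)."""
    pos = gen_follicle_positions(800, (1000, 1000), 25, seed=0)
    pat = PatternSpec(kind="reversed_patch", patch_center=(500, 500),
                      patch_radius=300)
    recs = gen_orientation_pattern(pos, pat, seed=100)
    return pos, recs, pat
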