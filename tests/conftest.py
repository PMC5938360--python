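import pandas as pd
import pytest

from mmgrowth import measure, synthetic


@pytest.fixture(scope="session")
def calibrated_config():
    """Measurement config with the diffraction offset calibrated against a
    rendered reference rod at the nominal outer diameter (0.78 μm)."""
    offset = measure.calibrate_diffraction_offset(0.78)
    return measure.MeasurementConfig(diffraction_offset=offset)


@pytest.fixture(scope="session")
def noisefree_scene():
    """Ten-cell scene at the study scale, rendered without noise."""
    spec = synthetic.typical_scene(rng_seed=3, n_cells=10)
    image, truth = synthetic.render_scene(spec, noiseless=True)
    return spec, image, truth


def pair_by_position(measured: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Match measured rows to ground-truth cells by position along the channel."""
    m = measured.sort_values("centroid_col_px").reset_index(drop=True)
    t = truth.sort_values("x_um").reset_index(drop=True)
    assert len(m) == len(t), f"{len(m)} measurements for {len(t)} cells"
    return pd.concat([m, t.add_prefix("true_")], axis=1)
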