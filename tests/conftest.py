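import dataclasses

import numpy as np
import pytest

from blockstorm.camera import SensorParams, simulate_sensor


@pytest.fixture
def p9_sensor() -> SensorParams:
    """Cellphone-sensor parameter set used throughout the calibration tests."""
    return SensorParams(
        gain=0.69, offset=4.1, read_noise=2.5, bit_depth=12, linear_max=4095, qe=0.75
    )


def intensity_ramp_frames(
    params: SensorParams,
    max_adu: float,
    n_frames: int = 10,
    shape: tuple[int, int] = (256, 256),
    seed: int = 1000,
    dark_fraction: float = 0.25,
) -> np.ndarray:
    """Repeated frames of a static horizontal intensity ramp.

    The leftmost ``dark_fraction`` of columns receive zero flux (the dark
    reference a photon-transfer series needs); the rest ramp linearly up to
    an expected ``max_adu`` ADU.
    """
    photons_max = max(0.0, max_adu - params.offset) * params.gain / params.qe
    h, w = shape
    col = np.clip(
        (np.linspace(0, 1, w) - dark_fraction) / (1 - dark_fraction), 0, 1
    )
    img = np.tile(col * photons_max, (h, 1))
    return np.stack(
        [simulate_sensor(img, params, seed=seed + i) for i in range(n_frames)]
    )


@pytest.fixture(scope="session")
def trained_end_to_end():
    """Train the GAN localizer once on a desk-scale dataset.

    Session-scoped because training takes minutes; the end-to-end recovery
    test and the artifact-suppression test share the same model.  Returns
    (model, acquisition config, held-out pairs, held-out ground truth).
    """
    from blockstorm.camera import load_sensor_preset
    from blockstorm.degradation import CompressionConfig
    from blockstorm.nn.gan import LossWeights, PsfKernel, TrainConfig, train
    from blockstorm.nn.models import DiscriminatorSpec, GeneratorSpec
    from blockstorm.simulate import AcquisitionConfig, make_training_pairs

    cfg = AcquisitionConfig(
        fov=(16, 16),
        pixel_size=100.0,
        psf_sigma=130.0,
        density=2.0,
        n_frames=256,
        photons_per_emitter=1000.0,
        photon_sigma_log=0.0,
        upsample=2,
        sensor=load_sensor_preset("huawei_p9_sec53"),
        compression=CompressionConfig(quality=90, mode="bespoke_transform"),
    )
    pairs, _ = make_training_pairs(cfg, seed=100)
    test_cfg = dataclasses.replace(cfg, n_frames=200)
    test_pairs, test_gt = make_training_pairs(test_cfg, seed=900)

    # PSF sigma on the map grid: 130 nm / (100 nm / 2x upsampling)
    model = train(
        pairs,
        GeneratorSpec(depth=3, base_channels=16),
        DiscriminatorSpec(n_layers=2, base_channels=16),
        LossWeights(),
        TrainConfig(learning_rate=1e-3, epochs=30, seed=7),
        psf=PsfKernel(sigma=2.6),
    )
    return model, cfg, test_pairs, test_gt
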