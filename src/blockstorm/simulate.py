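"""Ground-truth blinking-emitter simulation and training-pair generation.

Emitters blink independently frame by frame: per-frame counts are Poisson
with mean ``density * FOV area``, positions are uniform over the field of
view, and brightness is drawn log-normally around the configured mean photon
count.  Frames are rendered with a pixel-integrated Gaussian PSF, pushed
through the sensor and compression forward models, and paired with
single-pixel localization maps on an upsampled grid -- the (input, target)
pairs the network trains on.

Emitter tables are plain pandas DataFrames with columns
``frame, x, y, photons`` (x/y in nm); see :mod:`blockstorm.io` for the
ThunderSTORM-compatible CSV dialect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import erf

from .camera import SensorParams, simulate_sensor
from .degradation import CompressionConfig, block_transform_degrade, encode_decode_video

__all__ = [
    "AcquisitionConfig",
    "FramePair",
    "TABLE_COLUMNS",
    "sample_emitters",
    "render_frames",
    "render_location_maps",
    "make_training_pairs",
    "pairs_from_localizations",
    "mix_datasets",
    "upsample_nearest",
]

TABLE_COLUMNS = ("frame", "x", "y", "photons")


@dataclass(frozen=True)
class AcquisitionConfig:
    """Parameters of a simulated acquisition.

    fov is (height, width) in camera pixels; pixel_size is the effective
    size of one camera pixel in the sample plane (nm); density is the mean
    number of active emitters per square micrometre per frame.  When
    ``photon_sigma_log`` is zero every emitter carries exactly
    ``photons_per_emitter`` photons, otherwise brightness is log-normal
    around that mean.
    """

    fov: tuple[int, int] = (64, 64)
    pixel_size: float = 100.0
    psf_sigma: float = 130.0
    density: float = 4.0
    n_frames: int = 100
    photons_per_emitter: float = 1000.0
    photon_sigma_log: float = 0.3
    upsample: int = 5
    sensor: SensorParams | None = field(
        default_factory=lambda: SensorParams(
            gain=0.69, offset=4.1, read_noise=2.5, bit_depth=12, linear_max=220, qe=0.75
        )
    )
    compression: CompressionConfig | None = field(default_factory=CompressionConfig)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.psf_sigma <= 0:
            raise ValueError("pixel_size and psf_sigma must be > 0")
        if self.density < 0:
            raise ValueError("density must be >= 0")
        if self.upsample < 1:
            raise ValueError("upsample must be >= 1")

    @property
    def extent_nm(self) -> tuple[float, float]:
        """(height, width) of the FOV in nm."""
        return (self.fov[0] * self.pixel_size, self.fov[1] * self.pixel_size)

    @property
    def area_um2(self) -> float:
        h, w = self.extent_nm
        return (h / 1000.0) * (w / 1000.0)

    @property
    def map_pixel_nm(self) -> float:
        return self.pixel_size / self.upsample


@dataclass
class FramePair:
    """A degraded, upsampled input frame and its localization-map target."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        if self.x.shape != self.y.shape:
            raise ValueError(
                f"frame/map shape mismatch: {self.x.shape} vs {self.y.shape}"
            )


def sample_emitters(config: AcquisitionConfig, seed: int) -> pd.DataFrame:
    """Draw a ground-truth emitter table for one acquisition.

    Per frame the number of active emitters is Poisson(density * area);
    positions are uniform over the FOV; photons follow the configured
    brightness law.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    counts = rng.poisson(config.density * config.area_um2, size=config.n_frames)
    total = int(counts.sum())
    h_nm, w_nm = config.extent_nm
    frames = np.repeat(np.arange(config.n_frames), counts)
    x = rng.uniform(0.0, w_nm, size=total)
    y = rng.uniform(0.0, h_nm, size=total)
    mean = float(config.photons_per_emitter)
    if config.photon_sigma_log > 0:
        s = config.photon_sigma_log
        photons = rng.lognormal(np.log(mean) - 0.5 * s * s, s, size=total)
    else:
        photons = np.full(total, mean)
    return pd.DataFrame(
        {"frame": frames, "x": x, "y": y, "photons": photons}
    )


def _pixel_profile(centers_nm: np.ndarray, n_pix: int, pixel_nm: float,
                   sigma_nm: float) -> np.ndarray:
    """Per-emitter integrals of a 1-D Gaussian over each pixel. (E, n_pix)."""
    edges = np.arange(n_pix + 1) * pixel_nm
    z = (edges[None, :] - centers_nm[:, None]) / (sigma_nm * np.sqrt(2.0))
    cdf = 0.5 * (1.0 + erf(z))
    return np.diff(cdf, axis=1)


def render_frames(table: pd.DataFrame, config: AcquisitionConfig) -> np.ndarray:
    """Render noiseless expected-photon frames from an emitter table.

    Each emitter contributes ``photons`` times an isotropic Gaussian of
    standard deviation ``psf_sigma`` integrated over each pixel (error
    function rule); contributions add.
    """
    h, w = config.fov
    h_nm, w_nm = config.extent_nm
    stack = np.zeros((config.n_frames, h, w), dtype=np.float64)
    if len(table) == 0:
        return stack
    if ((table["x"] < 0) | (table["x"] >= w_nm)
            | (table["y"] < 0) | (table["y"] >= h_nm)).any():
        raise ValueError("emitter outside the field of view")
    if (table["frame"] < 0).any() or (table["frame"] >= config.n_frames).any():
        raise ValueError("emitter frame index outside [0, n_frames)")
    for f, sub in table.groupby("frame", sort=False):
        px = _pixel_profile(sub["x"].to_numpy(), w, config.pixel_size, config.psf_sigma)
        py = _pixel_profile(sub["y"].to_numpy(), h, config.pixel_size, config.psf_sigma)
        amp = sub["photons"].to_numpy()
        stack[int(f)] = np.einsum("e,ei,ej->ij", amp, py, px)
    return stack


def render_location_maps(table: pd.DataFrame, config: AcquisitionConfig) -> np.ndarray:
    """Render single-pixel localization maps on the upsampled grid.

    Each emitter sets the map pixel containing its position (index
    ``floor(coord / map_pixel)``) to its brightness; collisions sum.
    """
    h, w = config.fov
    u = config.upsample
    maps = np.zeros((config.n_frames, h * u, w * u), dtype=np.float64)
    if len(table) == 0:
        return maps
    mp = config.map_pixel_nm
    ix = np.clip(np.floor(table["x"].to_numpy() / mp).astype(int), 0, w * u - 1)
    iy = np.clip(np.floor(table["y"].to_numpy() / mp).astype(int), 0, h * u - 1)
    fr = table["frame"].to_numpy().astype(int)
    np.add.at(maps, (fr, iy, ix), table["photons"].to_numpy())
    return maps


def upsample_nearest(stack: np.ndarray, factor: int) -> np.ndarray:
    """Nearest-neighbour upsampling of (F, H, W) or (H, W) arrays."""
    if factor == 1:
        return np.asarray(stack, dtype=np.float64).copy()
    return np.repeat(np.repeat(stack, factor, axis=-2), factor, axis=-1).astype(
        np.float64
    )


def _compress_with_random_offset(
    frame: np.ndarray, config: CompressionConfig, rng: np.random.Generator
) -> np.ndarray:
    """Degrade with the block grid shifted by a random sub-block offset.

    Keeping the block grid fixed across a dataset would let a network key on
    the grid position instead of the artifact statistics, so the grid origin
    is randomized per frame.
    """
    b = config.block_size
    oy, ox = int(rng.integers(0, b)), int(rng.integers(0, b))
    padded = np.pad(frame, ((oy, 0), (ox, 0)), mode="edge")
    out = block_transform_degrade(padded, config)
    return out[oy:, ox:]


def make_training_pairs(
    config: AcquisitionConfig, seed: int
) -> tuple[list[FramePair], pd.DataFrame]:
    """Run the full forward pipeline and pair frames with their maps.

    Pipeline: sample emitters -> render expected photons -> sensor readout ->
    lossy compression (block grid randomly offset per frame) -> nearest-
    neighbour upsampling to the map grid.  Returns the pairs and the
    ground-truth table.
    """
    rng = np.random.default_rng(seed)
    table = sample_emitters(config, int(rng.integers(2**31)))
    clean = render_frames(table, config)
    maps = render_location_maps(table, config)

    frames = np.empty_like(clean)
    if config.sensor is not None:
        for i in range(clean.shape[0]):
            frames[i] = simulate_sensor(
                clean[i], config.sensor, int(rng.integers(2**31))
            )
    else:
        frames = np.rint(clean)

    if config.compression is not None:
        if config.compression.mode == "real_codec":
            frames = encode_decode_video(frames, config.compression)
        else:
            for i in range(frames.shape[0]):
                frames[i] = _compress_with_random_offset(
                    frames[i], config.compression, rng
                )

    up = upsample_nearest(frames, config.upsample)
    pairs = [FramePair(x=up[i], y=maps[i]) for i in range(up.shape[0])]
    return pairs, table


def pairs_from_localizations(
    stack: np.ndarray, detections: pd.DataFrame, config: AcquisitionConfig
) -> list[FramePair]:
    """Build training pairs from an already-degraded stack and a detection
    table produced by any localizer on that stack (training-label method B).
    """
    stack = np.asarray(stack, dtype=np.float64)
    if stack.shape[0] != config.n_frames:
        raise ValueError(
            f"stack has {stack.shape[0]} frames but config.n_frames="
            f"{config.n_frames}"
        )
    if len(detections) and (
        (detections["frame"] < 0) | (detections["frame"] >= config.n_frames)
    ).any():
        raise ValueError("detection frame index outside the stack")
    maps = render_location_maps(detections, config)
    up = upsample_nearest(stack, config.upsample)
    return [FramePair(x=up[i], y=maps[i]) for i in range(up.shape[0])]


def mix_datasets(a: list[FramePair], b: list[FramePair]) -> list[FramePair]:
    """Interleave two pair datasets in equal parts (50%/50%)."""
    n = min(len(a), len(b))
    mixed: list[FramePair] = []
    for i in range(n):
        mixed.append(a[i])
        mixed.append(b[i])
    return mixed
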