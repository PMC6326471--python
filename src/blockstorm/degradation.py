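"""Lossy-video forward model.

The dominant spatial artifact of consumer video codecs is blocking: each
frame is partitioned into 4x4 blocks, transformed with the exact-match
integer approximation of the DCT, and the coefficients are quantized.  This
module implements that transform/quantize/inverse round trip directly
(``bespoke_transform`` mode), a wrapper around a real H.264 encoder where one
is installed (``real_codec`` mode), and the temporal artifacts observed in
compressed dark series: a slow drift of the background plus periodic
intensity dips.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CompressionConfig",
    "CodecUnavailableError",
    "quant_step",
    "block_transform_degrade",
    "encode_decode_video",
    "inject_temporal_artifacts",
]

# Exact-match 4x4 integer transform (rows orthogonal, norms 4,10,4,10).
TRANSFORM = np.array(
    [
        [1, 1, 1, 1],
        [2, 1, -1, -2],
        [1, -1, -1, 1],
        [1, -2, 2, -1],
    ],
    dtype=np.float64,
)
_ROW_NORMS = np.array([4.0, 10.0, 4.0, 10.0])
# C^-1 = C^T diag(1/norms); exact because the rows are orthogonal.
_INV = TRANSFORM.T / _ROW_NORMS
# Coefficient normalization: raw coefficient (i, j) is scaled up by
# |r_i| * |r_j| relative to the pixel amplitudes, so the quantizer applies
# its step to Y / SCALING (H.264 folds exactly this normalization into its
# quantization tables).  Quantizing raw coefficients instead would make the
# effective pixel-domain step q/|r_i||r_j| -- up to ten times finer than q
# and too gentle to ever imprint the block grid.
SCALING = np.sqrt(np.outer(_ROW_NORMS, _ROW_NORMS))


class CodecUnavailableError(RuntimeError):
    """No H.264 encoder is installed on this system."""


@dataclass(frozen=True)
class CompressionConfig:
    """Settings of the lossy-compression stage.

    quality maps to the quantization step via
    ``q = max(1, round(2**((100 - quality)/12.5)))``: the step doubles every
    12.5 quality points and quality 100 is lossless.
    """

    quality: float = 90.0
    block_size: int = 4
    mode: str = "bespoke_transform"
    gop_period: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.quality <= 100:
            raise ValueError(f"quality must be in [1, 100], got {self.quality}")
        if self.block_size < 2:
            raise ValueError(f"block_size must be >= 2, got {self.block_size}")
        if self.mode not in ("bespoke_transform", "real_codec"):
            raise ValueError(f"unknown compression mode {self.mode!r}")


def quant_step(quality: float) -> int:
    """Quantization step for a quality percentage (q(100) = 1)."""
    return max(1, int(round(2.0 ** ((100.0 - quality) / 12.5))))


def block_transform_degrade(
    frame: np.ndarray, config: CompressionConfig
) -> np.ndarray:
    """Degrade a frame with the 4x4 integer-transform quantizer.

    Edge blocks are replicate-padded; the output is cropped back and clipped
    to the input's value range rounded to the enclosing power-of-two bit
    range.
    """
    if config.mode != "bespoke_transform":
        raise ValueError("block_transform_degrade requires mode='bespoke_transform'")
    if config.block_size != 4:
        raise ValueError("bespoke mode implements the 4x4 integer transform only")
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise ValueError(f"frame must be 2-D, got shape {frame.shape}")

    h, w = frame.shape
    ph = (-h) % 4
    pw = (-w) % 4
    padded = np.pad(frame, ((0, ph), (0, pw)), mode="edge")
    hh, ww = padded.shape

    blocks = padded.reshape(hh // 4, 4, ww // 4, 4).transpose(0, 2, 1, 3)
    q = quant_step(config.quality)
    # Y = C X C^T per block; uniform quantization of the normalized
    # coefficients (step q * |r_i||r_j|, i.e. step q in pixel amplitude
    # units); exact inverse.  q = 1 skips quantization entirely, which is
    # exact on integer frames because the transform pair is exact.
    coeff = np.einsum("ij,abjk,lk->abil", TRANSFORM, blocks, TRANSFORM)
    if q > 1:
        step = q * SCALING
        coeff = np.round(coeff / step) * step
    recon = np.einsum("ij,abjk,lk->abil", _INV, coeff, _INV)
    out = recon.transpose(0, 2, 1, 3).reshape(hh, ww)[:h, :w]

    out = np.rint(out)
    lo = min(0.0, float(frame.min()))
    hi_in = float(frame.max())
    bits = max(1, int(np.ceil(np.log2(hi_in + 1))) if hi_in >= 1 else 1)
    hi = max(hi_in, 2.0**bits - 1)
    return np.clip(out, lo, hi)


def encode_decode_video(
    stack: np.ndarray, config: CompressionConfig, fps: float = 20.0
) -> np.ndarray:
    """Round-trip a stack through a real H.264 encoder, if one is installed.

    Frames are scaled to 8-bit luma, encoded at a constant rate factor
    derived from ``config.quality`` and decoded back to the input scale.

    Raises
    ------
    CodecUnavailableError
        When no H.264 encoder (ffmpeg) is available; use
        ``mode='bespoke_transform'`` with :func:`block_transform_degrade`
        instead.
    """
    if config.mode != "real_codec":
        raise ValueError("encode_decode_video requires mode='real_codec'")
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim != 3:
        raise ValueError("stack must be (frames, H, W)")
    try:
        import imageio.v2 as iio
        import imageio_ffmpeg  # noqa: F401
    except ImportError as exc:
        raise CodecUnavailableError(
            "no H.264 encoder available (imageio-ffmpeg/ffmpeg not installed); "
            "use CompressionConfig(mode='bespoke_transform') with "
            "block_transform_degrade instead"
        ) from exc

    import tempfile
    from pathlib import Path

    vmax = float(stack.max())
    scale = 255.0 / vmax if vmax > 0 else 1.0
    frames8 = np.clip(np.rint(stack * scale), 0, 255).astype(np.uint8)
    crf = int(round(51 * (1.0 - config.quality / 100.0)))
    with tempfile.TemporaryDirectory() as td:
        path = str(Path(td) / "roundtrip.mp4")
        writer = iio.get_writer(
            path, fps=fps, codec="libx264", output_params=["-crf", str(crf)],
            macro_block_size=1,
        )
        for f in frames8:
            writer.append_data(f)
        writer.close()
        reader = iio.get_reader(path)
        decoded = np.stack(
            [np.asarray(f, dtype=np.float64)[..., 0] if np.ndim(f) == 3 else f
             for f in reader], axis=0
        )
        reader.close()
    if decoded.shape != frames8.shape:
        decoded = decoded[: frames8.shape[0], : frames8.shape[1], : frames8.shape[2]]
    return decoded / scale


def inject_temporal_artifacts(
    stack: np.ndarray,
    drift_slope: float = 0.0,
    dip_depth: float = 0.0,
    dip_period: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Add a global linear intensity ramp and periodic dips to a stack.

    Every ``dip_period``-th frame loses ``dip_depth`` ADU; the drift adds
    ``drift_slope * frame_index`` ADU to every pixel.  Values below zero are
    clipped.
    """
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim != 3:
        raise ValueError("stack must be (frames, H, W)")
    if dip_period is not None and dip_period < 1:
        raise ValueError("dip_period must be >= 1 (or None to disable dips)")
    n = stack.shape[0]
    delta = drift_slope * np.arange(n, dtype=np.float64)
    if dip_period is not None and dip_depth != 0.0:
        dips = np.zeros(n)
        dips[dip_period - 1 :: dip_period] = dip_depth
        delta = delta - dips
    out = stack + delta[:, None, None]
    return np.clip(out, 0.0, None)
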