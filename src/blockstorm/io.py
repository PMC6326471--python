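"""File formats: TIFF/MP4 stacks, ThunderSTORM-dialect CSV tables, YAML
configuration and run manifests.

The localization-table dialect is ThunderSTORM's: a header of
``id,frame,x [nm],y [nm],intensity [photon]`` (plus optional ``sigma [nm]``
and ``background`` columns) so tables open directly in existing SMLM
viewers.  Decimal commas are never emitted.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "read_stack",
    "write_stack",
    "read_table",
    "write_table",
    "load_run_config",
    "write_manifest",
]

_COLMAP = {
    "frame": "frame",
    "x [nm]": "x",
    "y [nm]": "y",
    "intensity [photon]": "photons",
    "sigma [nm]": "sigma",
    "background": "background",
}
_REQUIRED = ("frame", "x [nm]", "y [nm]")


def read_stack(path: str | Path) -> np.ndarray:
    """Read a frame stack from a multi-page TIFF or an MP4 video.

    MP4 frames are decoded to grayscale luma.  Raises ``ValueError`` on an
    unsupported container.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(str(path))
        return arr[None] if arr.ndim == 2 else arr
    if suffix in (".mp4", ".avi", ".mov"):
        import imageio.v2 as iio

        reader = iio.get_reader(str(path))
        frames = []
        for f in reader:
            f = np.asarray(f)
            if f.ndim == 3:
                f = f[..., 0]
            frames.append(f)
        reader.close()
        return np.stack(frames)
    raise ValueError(
        f"unsupported stack container {suffix!r} (expected .tif/.tiff or .mp4)"
    )


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    """Write a stack as multi-page TIFF (lossless round trip)."""
    path = Path(path)
    if path.suffix.lower() not in (".tif", ".tiff"):
        raise ValueError(f"write_stack writes TIFF only, got {path.suffix!r}")
    stack = np.asarray(stack)
    kwargs = {"photometric": "minisblack"} if stack.ndim == 3 else {}
    tifffile.imwrite(str(path), stack, **kwargs)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a ThunderSTORM-dialect localization CSV.

    Returns a DataFrame with columns ``frame, x, y`` plus any of
    ``photons, sigma, background`` present in the file.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().strip('"') for c in df.columns]
    for col in _REQUIRED:
        if col not in df.columns:
            raise ValueError(f"missing mandatory column {col!r} in {path}")
    out = pd.DataFrame()
    for src, dst in _COLMAP.items():
        if src in df.columns:
            out[dst] = df[src]
    out["frame"] = out["frame"].astype(int)
    return out


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a localization table in the ThunderSTORM CSV dialect."""
    out = pd.DataFrame()
    out["id"] = np.arange(1, len(table) + 1)
    out["frame"] = table["frame"].astype(int).to_numpy()
    out["x [nm]"] = table["x"].to_numpy(dtype=float)
    out["y [nm]"] = table["y"].to_numpy(dtype=float)
    if "sigma" in table.columns:
        out["sigma [nm]"] = table["sigma"].to_numpy(dtype=float)
    if "photons" in table.columns:
        out["intensity [photon]"] = table["photons"].to_numpy(dtype=float)
    if "background" in table.columns:
        out["background"] = table["background"].to_numpy(dtype=float)
    out.to_csv(path, index=False, float_format="%.4f")


def load_run_config(path: str | Path) -> dict:
    """Load a YAML run configuration into nested config objects.

    Recognized sections: acquisition, sensor, compression, detection, loss,
    training, paths, seed.  Returns a dict of constructed objects plus the
    raw mapping under ``"raw"``.
    """
    from .baseline import DetectionConfig
    from .camera import SensorParams, load_sensor_preset
    from .degradation import CompressionConfig
    from .nn.gan import LossWeights, TrainConfig
    from .simulate import AcquisitionConfig

    raw = yaml.safe_load(Path(path).read_text()) or {}
    out: dict = {"raw": raw, "seed": int(raw.get("seed", 0))}

    sensor = None
    if "sensor" in raw:
        s = raw["sensor"]
        sensor = load_sensor_preset(s) if isinstance(s, str) else SensorParams(**s)
    compression = None
    if "compression" in raw:
        compression = CompressionConfig(**raw["compression"])
    if "acquisition" in raw:
        acq = dict(raw["acquisition"])
        if "fov" in acq:
            acq["fov"] = tuple(acq["fov"])
        acq.setdefault("sensor", sensor)
        acq.setdefault("compression", compression)
        out["acquisition"] = AcquisitionConfig(**acq)
    if sensor is not None:
        out["sensor"] = sensor
    if compression is not None:
        out["compression"] = compression
    if "detection" in raw:
        out["detection"] = DetectionConfig(**raw["detection"])
    if "loss" in raw:
        out["loss"] = LossWeights(**raw["loss"])
    if "training" in raw:
        out["training"] = TrainConfig(**raw["training"])
    out["paths"] = raw.get("paths", {})
    return out


def write_manifest(path: str | Path, config: dict, seed: int,
                   outputs: list[str]) -> None:
    """Write a JSON manifest recording config hash, seed and outputs."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "config": config,
        "seed": seed,
        "outputs": outputs,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
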