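"""Readers and writers for the pipeline's on-disk formats.

Stacks are multi-page TIFF (one page per frame, float or 8-bit RGB);
masks are single-page PNG or TIFF with 0/255 coding (any nonzero pixel
reads as True); activity maps go out as 32-bit float TIFF plus an NPZ
bundle with the constituent maps and band metadata; reports and
manifests are JSON. Every writer uses the (row, col) top-left origin,
row-major convention with time first in stacks.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .preprocess import ReflectanceSequence
from .spectral import ActivityMap

__all__ = [
    "read_mask", "write_mask", "read_stack", "write_stack",
    "write_report", "read_report", "write_activity_map",
    "read_activity_map", "sha256_of",
]


def write_mask(path: str | Path, mask: np.ndarray) -> Path:
    """Write a boolean mask as an 8-bit 0/255 image (PNG or TIFF)."""
    path = Path(path)
    data = (np.asarray(mask, dtype=bool).astype(np.uint8)) * 255
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)
    return path


def read_mask(path: str | Path, expected_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Read a mask image; any nonzero pixel is True."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        data = iio.imread(path)
    if data.ndim == 3:  # collapse RGB(A) mask renderings
        data = data[..., :3].max(axis=-1)
    mask = np.asarray(data) != 0
    if expected_shape is not None and mask.shape != tuple(expected_shape):
        raise ValueError(
            f"mask {path} has shape {mask.shape}, expected {tuple(expected_shape)}"
        )
    return mask


def write_stack(path: str | Path, frames: np.ndarray) -> Path:
    """Write a (time, rows, cols[, 3]) stack as multi-page TIFF.

    Float stacks are stored as 32-bit float; integer (RGB) stacks keep
    their dtype.
    """
    path = Path(path)
    frames = np.asarray(frames)
    if frames.dtype.kind == "f":
        frames = frames.astype(np.float32)
    tifffile.imwrite(path, frames)
    return path


def read_stack(
    path: str | Path,
    frame_interval: float,
    channel_origin: str = "filtered_568nm",
) -> ReflectanceSequence:
    """Read a multi-page TIFF stack as a ReflectanceSequence.

    RGB pages are rejected here — run the green-channel extraction on
    the raw 4-D array instead (see :func:`read_rgb_stack`).
    """
    frames = tifffile.imread(Path(path))
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError(
            f"stack {path} has shape {frames.shape}; expected (time, rows, cols) — "
            "for RGB data use read_rgb_stack + extract_green_channel"
        )
    return ReflectanceSequence(
        frames=frames.astype(np.float64),
        frame_interval=frame_interval,
        channel_origin=channel_origin,
        preprocessing_log=[f"read_stack({Path(path).name})"],
    )


def read_rgb_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page RGB TIFF as a (time, rows, cols, 3) array."""
    stack = tifffile.imread(Path(path))
    if stack.ndim == 3 and stack.shape[-1] == 3:
        stack = stack[None]
    if stack.ndim != 4 or stack.shape[-1] != 3:
        raise ValueError(f"{path} is not an RGB stack (shape {stack.shape})")
    return stack


class _NumpyJSONEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_report(path: str | Path, report: dict) -> Path:
    """Write a report/manifest dict as stable, sorted-key JSON."""
    path = Path(path)
    path.write_text(
        json.dumps(report, cls=_NumpyJSONEncoder, indent=2, sort_keys=True) + "\n"
    )
    return path


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_activity_map(out_dir: str | Path, amap: ActivityMap) -> dict[str, Path]:
    """Write ratio as float TIFF plus an NPZ bundle with constituents."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ratio_path = out_dir / "ratio.tif"
    tifffile.imwrite(ratio_path, amap.ratio.astype(np.float32))
    bundle_path = out_dir / "activity_bundle.npz"
    np.savez(
        bundle_path,
        ratio=amap.ratio,
        p_s=amap.p_s,
        p_vlf=amap.p_vlf,
        f_stim=amap.f_stim,
        vlf_band=np.asarray(amap.vlf_band),
        excluded_bins=np.asarray(amap.excluded_bins, dtype=np.int64),
        stim_bin=amap.stim_bin,
        n_zero_vlf_pixels=amap.n_zero_vlf_pixels,
    )
    return {"ratio": ratio_path, "bundle": bundle_path}


def read_activity_map(out_dir: str | Path) -> ActivityMap:
    with np.load(Path(out_dir) / "activity_bundle.npz") as z:
        return ActivityMap(
            ratio=z["ratio"],
            p_s=z["p_s"],
            p_vlf=z["p_vlf"],
            f_stim=float(z["f_stim"]),
            vlf_band=tuple(z["vlf_band"].tolist()),
            excluded_bins=z["excluded_bins"].tolist(),
            stim_bin=int(z["stim_bin"]),
            n_zero_vlf_pixels=int(z["n_zero_vlf_pixels"]),
        )


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
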