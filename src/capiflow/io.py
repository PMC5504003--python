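"""File formats: multi-page TIFF video stacks with JSON sidecars,
cohort CSV tables, visual-field JSON and kymograph TIFF output."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from capiflow.sim.cohort import COHORT_COLUMNS
from capiflow.stack import VideoStack
from capiflow.velocimetry.kymograph import Kymograph
from capiflow.vf24 import VFTest

__all__ = [
    "sidecar_path",
    "write_video_stack",
    "read_video_stack",
    "write_kymograph",
    "write_cohort",
    "read_cohort",
    "write_vf_tests",
    "read_vf_tests",
]


def sidecar_path(tiff_path: str | Path) -> Path:
    return Path(tiff_path).with_suffix(".json")


def write_video_stack(
    path: str | Path, stack: VideoStack, *, seed: int | None = None,
    bits: int = 16,
) -> Path:
    """Write a stack as grayscale multi-page TIFF plus a JSON sidecar.

    Intensities in [0, 1] are scaled to the full 8- or 16-bit range.
    Returns the sidecar path.
    """
    if bits not in (8, 16):
        raise ValueError("bits must be 8 or 16")
    dtype = np.uint8 if bits == 8 else np.uint16
    scale = np.iinfo(dtype).max
    data = np.clip(np.asarray(stack.frames, dtype=float), 0.0, 1.0)
    tifffile.imwrite(path, (data * scale).astype(dtype))
    meta = {
        "fps": stack.fps,
        "field_deg": list(stack.field_deg),
        "axial_length_mm": stack.axial_length_mm,
        "bits": bits,
    }
    if seed is not None:
        meta["seed"] = seed
    side = sidecar_path(path)
    side.write_text(json.dumps(meta, indent=2))
    return side


def read_video_stack(
    path: str | Path, meta_path: str | Path | None = None
) -> VideoStack:
    """Read a multi-page TIFF and its JSON sidecar back into a stack."""
    meta_path = Path(meta_path) if meta_path else sidecar_path(path)
    meta = json.loads(Path(meta_path).read_text())
    raw = tifffile.imread(path)
    if raw.ndim == 2:
        raw = raw[None]
    frames = raw.astype(float) / np.iinfo(raw.dtype).max
    return VideoStack(
        frames=frames,
        fps=float(meta["fps"]),
        field_deg=tuple(meta["field_deg"]),
        axial_length_mm=float(meta["axial_length_mm"]),
    )


def write_kymograph(path: str | Path, kymo: Kymograph) -> None:
    """Write a kymograph as 16-bit TIFF (intensities stretched to range)."""
    img = kymo.image
    lo, hi = img.min(), img.max()
    norm = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    tifffile.imwrite(path, (norm * 65535).astype(np.uint16))


def write_cohort(path: str | Path, cohort: pd.DataFrame) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    cohort = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return cohort


def write_vf_tests(path: str | Path, tests: dict[str, VFTest]) -> None:
    """Serialise visual-field tests keyed by subject id."""
    Path(path).write_text(
        json.dumps({sid: vf.to_dict() for sid, vf in tests.items()}, indent=2)
    )


def read_vf_tests(path: str | Path) -> dict[str, VFTest]:
    raw = json.loads(Path(path).read_text())
    return {sid: VFTest.from_dict(d) for sid, d in raw.items()}
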