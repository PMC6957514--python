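"""Shared I/O: calibrated image stacks with JSON sidecars, run manifests.

Every physical-unit computation in the package requires calibration
(pixel size, frame interval), which travels in a JSON sidecar next to the
pixel data, never inside array values.  Stacks are written as 32-bit float
TIFF (one file per channel) or NPZ; reading without a sidecar is allowed
only for uncalibrated previews.
"""

from __future__ import annotations

import dataclasses
import json
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import tifffile


@dataclass
class SidecarMetadata:
    """Calibration and channel-role metadata for an image stack.

    pixel_size is in the unit named by ``pixel_unit`` ("nm" or "um") per
    pixel; frame_interval is in seconds.
    """

    pixel_size: float
    pixel_unit: str = "nm"
    frame_interval: float = 1.0
    channel: str = "height"
    height_reference: str | None = None
    seed: int | None = None
    extra: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.pixel_unit not in ("nm", "um"):
            raise ValueError("pixel_unit must be 'nm' or 'um'")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    def pixel_size_nm(self) -> float:
        return self.pixel_size * (1e3 if self.pixel_unit == "um" else 1.0)

    def pixel_size_um(self) -> float:
        return self.pixel_size * (1e-3 if self.pixel_unit == "nm" else 1.0)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SidecarMetadata":
        known = {f.name for f in dataclasses.fields(cls)}
        core = {k: v for k, v in d.items() if k in known}
        extra = {k: v for k, v in d.items() if k not in known}
        if extra:
            core.setdefault("extra", {}).update(extra)
        return cls(**core)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_image_stack(path: str | Path, stack: np.ndarray, meta: SidecarMetadata) -> Path:
    """Write a (frame, row, col) stack as float32 TIFF or NPZ plus sidecar."""
    path = Path(path)
    stack = np.asarray(stack, dtype=np.float32)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError("stack must be 2-D or 3-D (frame, row, col)")
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, stack)
    elif path.suffix.lower() == ".npz":
        np.savez_compressed(path, stack=stack)
    else:
        raise ValueError(f"unsupported stack format: {path.suffix}")
    _sidecar_path(path).write_text(json.dumps(meta.to_dict(), indent=1))
    return path


def read_image_stack(
    path: str | Path, require_sidecar: bool = True
) -> tuple[np.ndarray, SidecarMetadata | None]:
    """Read a stack plus its sidecar.

    With require_sidecar=True (the default for any calibrated analysis) a
    missing sidecar is a hard error: the package never produces
    physical-unit results from uncalibrated pixels.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        stack = tifffile.imread(path)
    elif path.suffix.lower() == ".npz":
        with np.load(path) as f:
            stack = f["stack"]
    else:
        raise ValueError(f"unsupported stack format: {path.suffix}")
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim == 2:
        stack = stack[None]
    if not np.all(np.isfinite(stack)):
        raise ValueError(f"{path} contains non-finite pixels")
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = SidecarMetadata.from_dict(json.loads(sidecar.read_text()))
    elif require_sidecar:
        raise FileNotFoundError(
            f"no JSON sidecar next to {path}; calibrated analyses refuse "
            "uncalibrated stacks (pass require_sidecar=False for a preview)"
        )
    else:
        meta = None
    return stack, meta


def write_json(path: str | Path, payload: Any) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o: Any) -> Any:
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(payload, indent=1, default=default))
    return path


def read_json(path: str | Path) -> Any:
    return json.loads(Path(path).read_text())


def write_manifest(
    out_dir: str | Path,
    stage: str,
    params: dict[str, Any],
    seed: int | None,
    inputs: list[str] | None = None,
    outputs: list[str] | None = None,
) -> Path:
    """Write a run manifest sufficient to reproduce a deterministic stage."""
    from memkin import __version__

    manifest = {
        "stage": stage,
        "params": params,
        "seed": seed,
        "inputs": inputs or [],
        "outputs": outputs or [],
        "package_version": __version__,
        "python": platform.python_version(),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    return write_json(Path(out_dir) / "manifest.json", manifest)
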