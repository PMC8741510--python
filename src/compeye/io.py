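"""Readers, writers, configuration and run manifests.

Images travel as TIFF (32-bit float for height maps) or PNG; tables are
UTF-8 CSV with a header row; summaries are JSON.  Every CLI run writes a
manifest (config + seeds + input hashes) sufficient to reproduce its
outputs exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .allometry import LANDMARKS, LandmarkRecord
from .psychophysics import WBATrial
from .stack import EyeSurface, FocusStack
from .exceptions import ValidationError

__all__ = [
    "RunConfig",
    "read_stack",
    "write_surface",
    "read_landmarks",
    "read_trials",
    "write_trials",
    "write_report",
    "write_manifest",
]


@dataclass
class RunConfig:
    """Stage parameters with the study's stated values as defaults."""

    window: int = 5                     # focus-metric window, px
    mask_threshold: float = 0.1         # fraction of max focus score
    lowpass_factor: float = 1.25        # x fundamental radius
    n_center: int = 300                 # facets averaged for D
    n_boot: int = 10_000                # bootstrap replicates
    ci_level: float = 0.99              # detection CI
    response_window: tuple = (0.5, 2.0)  # s after presentation
    still_period: float = 0.2           # s baseline epoch
    seed: int = 0
    delta_h: float | None = None        # um, stack metadata
    pixel_scale: float | None = None    # um/px, stack metadata

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "response_window" in data and data["response_window"] is not None:
            data["response_window"] = tuple(data["response_window"])
        return cls(**data)


def read_stack(path: str | Path, delta_h: float,
               pixel_scale: float) -> FocusStack:
    """Load a focus stack from a multipage TIFF or a directory of images.

    Directory entries (PNG/TIFF) are ordered by filename.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".png", ".tif", ".tiff"))
        if not files:
            raise ValidationError(f"no PNG/TIFF layers found in {path}")
        layers = [np.asarray(iio.imread(f), dtype=float) for f in files]
        shapes = {l.shape for l in layers}
        if len(shapes) != 1:
            raise ValidationError(f"layer shapes differ: {shapes}")
        arr = np.stack(layers)
    else:
        arr = np.asarray(tifffile.imread(path), dtype=float)
        if arr.ndim == 2:
            raise ValidationError("TIFF has a single page; need >= 2 layers")
    return FocusStack(layers=arr, delta_h=delta_h, pixel_scale=pixel_scale)


def write_stack(stack: FocusStack, path: str | Path) -> None:
    """Write a stack as a multipage float32 TIFF with unit metadata."""
    tifffile.imwrite(
        Path(path), stack.layers.astype(np.float32),
        metadata={"delta_h_um": stack.delta_h,
                  "pixel_scale_um": stack.pixel_scale},
    )


def write_surface(surface: EyeSurface, out_dir: str | Path) -> dict:
    """Write heights (float32 TIFF, um), mask (PNG) and composite (TIFF)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "heights": out / "heights.tif",
        "mask": out / "mask.png",
        "composite": out / "composite.tif",
    }
    tifffile.imwrite(paths["heights"], surface.heights.astype(np.float32),
                     metadata={"units": "um",
                               "delta_h_um": surface.delta_h,
                               "pixel_scale_um": surface.pixel_scale})
    iio.imwrite(paths["mask"], (surface.mask * 255).astype(np.uint8))
    tifffile.imwrite(paths["composite"], surface.composite.astype(np.float32))
    return {k: str(v) for k, v in paths.items()}


def read_landmarks(path: str | Path) -> list[LandmarkRecord]:
    """Landmark CSV: specimen_id, genotype, ax, ay, ..., hx, hy[, scale].

    Coordinates are multiplied by the per-row ``scale`` (um per pixel,
    default 1) so records come out in micrometers.
    """
    df = pd.read_csv(path)
    needed = ["specimen_id", "genotype"] + [f"{k}{ax}" for k in LANDMARKS
                                            for ax in "xy"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValidationError(f"landmark CSV missing columns: {missing}")
    records = []
    for i, row in df.iterrows():
        scale = float(row.get("scale", 1.0)) if "scale" in df.columns else 1.0
        try:
            pts = {k: (scale * float(row[f"{k}x"]), scale * float(row[f"{k}y"]))
                   for k in LANDMARKS}
            records.append(LandmarkRecord(str(row["specimen_id"]),
                                          str(row["genotype"]), pts))
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"landmark CSV row {i}: {exc}") from exc
    return records


_TRIAL_COLS = ["fly_id", "trace_file", "contrast", "spatial_frequency",
               "temporal_frequency", "direction", "lighting", "experiment"]


def write_trials(trials: list[WBATrial], out_dir: str | Path) -> Path:
    """Write an index CSV plus one two-column trace CSV per trial."""
    out = Path(out_dir)
    traces = out / "traces"
    traces.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, t in enumerate(trials):
        fname = f"trial{i:05d}.csv"
        pd.DataFrame({"left": t.left, "right": t.right}).to_csv(
            traces / fname, index=False)
        rows.append({"fly_id": t.fly_id, "trace_file": f"traces/{fname}",
                     "contrast": t.contrast,
                     "spatial_frequency": t.spatial_frequency,
                     "temporal_frequency": t.temporal_frequency,
                     "direction": t.direction, "lighting": t.lighting,
                     "experiment": t.experiment})
    index = out / "trials.csv"
    pd.DataFrame(rows, columns=_TRIAL_COLS).to_csv(index, index=False)
    return index


def read_trials(path: str | Path) -> list[WBATrial]:
    """Read the trial index CSV written by :func:`write_trials`."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValidationError(f"trial index {path} contains no trials")
    missing = [c for c in _TRIAL_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"trial CSV missing columns: {missing}")
    trials = []
    for i, row in df.iterrows():
        trace = pd.read_csv(path.parent / row["trace_file"])
        if not {"left", "right"} <= set(trace.columns):
            raise ValidationError(
                f"trace file {row['trace_file']} (row {i}) needs "
                "'left' and 'right' columns"
            )
        trials.append(WBATrial(
            fly_id=str(row["fly_id"]),
            left=trace["left"].to_numpy(),
            right=trace["right"].to_numpy(),
            contrast=float(row["contrast"]),
            spatial_frequency=float(row["spatial_frequency"]),
            temporal_frequency=float(row["temporal_frequency"]),
            direction=str(row["direction"]),
            lighting=float(row["lighting"]),
            experiment=str(row["experiment"]),
        ))
    return trials


def write_report(results: dict, path: str | Path) -> None:
    """JSON summary writer (numpy types coerced to plain Python)."""

    def default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    Path(path).write_text(json.dumps(results, indent=2, default=default))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: str | Path, config: RunConfig,
                   inputs: list[str | Path] = ()) -> Path:
    """Record config, seed and input hashes next to a run's outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": asdict(config),
        "inputs": {str(p): _sha256(Path(p)) for p in inputs
                   if Path(p).is_file()},
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
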