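"""Image and table I/O for the dystrophin quantification pipeline.

The canonical image input is a multi-channel TIFF holding one dystrophin
and one spectrin plane on the 12-bit acquisition scale (0--4095 arbitrary
units).  Confocal vendors store calibration in proprietary metadata, so the
pixel size (um/pixel) is always supplied by the caller, either directly or
through a YAML config.  Fiber-level results are written as plain CSV with a
fixed column order so that downstream statistics can be re-run from files
alone.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

MAX_INTENSITY = 4095.0  # 12-bit acquisition scale, arbitrary units


class FormatError(ValueError):
    """Raised when an input file does not match the declared layout."""


class ValidationError(ValueError):
    """Raised when image data violates the 12-bit intensity contract."""


@dataclasses.dataclass
class SectionImage:
    """One imaged field of a muscle cross-section (two registered channels).

    Parameters
    ----------
    dystrophin, spectrin
        2-D float arrays of identical shape, intensities in arbitrary
        units on the 12-bit scale [0, 4095].
    pixel_size
        Lateral calibration in micrometres per pixel (> 0).
    biopsy_id, section_id, image_id
        Provenance labels used to key fibers into the
        biopsy -> section -> image hierarchy.
    staining_combo
        Antibody-pair label (e.g. the dystrophin/spectrin clone pair).
    is_isotype_control
        True for isotype-stained background-assessment images.
    bead_reference_intensity
        Optional calibration-bead intensity carried as metadata; never
        applied to the data unless normalisation is explicitly requested.
    """

    dystrophin: np.ndarray
    spectrin: np.ndarray
    pixel_size: float
    biopsy_id: str = ""
    section_id: str = ""
    image_id: str = ""
    staining_combo: str = ""
    is_isotype_control: bool = False
    bead_reference_intensity: float | None = None

    def __post_init__(self) -> None:
        self.dystrophin = np.asarray(self.dystrophin, dtype=np.float64)
        self.spectrin = np.asarray(self.spectrin, dtype=np.float64)
        if self.dystrophin.ndim != 2 or self.spectrin.ndim != 2:
            raise ValidationError("channels must be 2-D intensity grids")
        if self.dystrophin.shape != self.spectrin.shape:
            raise ValidationError(
                f"channel shapes disagree: dystrophin {self.dystrophin.shape} "
                f"vs spectrin {self.spectrin.shape}"
            )
        if not (self.pixel_size > 0):
            raise ValidationError("pixel_size must be strictly positive")
        for name, chan in (("dystrophin", self.dystrophin), ("spectrin", self.spectrin)):
            if not np.all(np.isfinite(chan)):
                raise ValidationError(f"non-finite values in {name} channel")
            if chan.min() < 0 or chan.max() > MAX_INTENSITY:
                raise ValidationError(
                    f"{name} channel outside 12-bit range [0, {MAX_INTENSITY:.0f}]"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.dystrophin.shape


@dataclasses.dataclass
class AnalysisConfig:
    """Tunable parameters of the segmentation/quantification pipeline.

    All physical parameters are in micrometres; conversion to pixels
    happens inside the operations using each image's own calibration.
    """

    membrane_max_thickness_um: float = 3.0
    min_fiber_area_um2: float = 200.0
    max_fiber_area_um2: float = 20000.0
    quantile_levels: tuple[float, ...] = (0.1, 0.25, 0.5, 0.75, 0.9)
    revertant_threshold_au: float = 800.0
    trace_floor_au: float = 200.0
    # segmentation tuning
    smoothing_sigma_um: float = 1.0
    ridge_threshold_method: str = "otsu"  # "otsu" | "percentile" (both gain-relative)
    ridge_threshold_fraction: float = 0.35  # percentile method: position between lo/hi
    ridge_percentile_low: float = 10.0
    ridge_percentile_high: float = 99.0
    seed_min_area_um2: float = 100.0
    enclosure_min_fraction: float = 0.5
    membrane_min_perimeter_fraction: float = 0.6
    random_seed: int = 0

    def __post_init__(self) -> None:
        levels = tuple(sorted(float(q) for q in self.quantile_levels))
        if any(not (0.0 < q < 1.0) for q in levels):
            raise ValueError("quantile levels must lie strictly inside (0, 1)")
        if not any(abs(q - 0.9) < 1e-12 for q in levels):
            levels = tuple(sorted(levels + (0.9,)))
        self.quantile_levels = levels
        if not (self.membrane_max_thickness_um > 0):
            raise ValueError("membrane_max_thickness_um must be > 0")
        if not (self.min_fiber_area_um2 > 0):
            raise ValueError("min_fiber_area_um2 must be > 0")
        if not (0 <= self.trace_floor_au < self.revertant_threshold_au):
            raise ValueError("require 0 <= trace_floor_au < revertant_threshold_au")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "quantile_levels" in data:
            data["quantile_levels"] = tuple(data["quantile_levels"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["quantile_levels"] = list(data["quantile_levels"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def load_section_image(
    path: str | Path,
    channel_map: Mapping[str, int],
    pixel_size: float,
    meta: Mapping[str, object] | None = None,
) -> SectionImage:
    """Read a multi-channel TIFF and extract the two analysis channels.

    ``channel_map`` assigns plane indices, e.g. ``{"dystrophin": 0,
    "spectrin": 1}``.  8/12/16-bit storage is accepted; values are
    interpreted on the 12-bit au scale without rescaling.  Values outside
    [0, 4095] raise a validation error naming the offending channel.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    planes = tifffile.imread(path)
    planes = np.asarray(planes)
    if planes.ndim == 2:
        planes = planes[None]
    if planes.ndim != 3:
        raise FormatError(f"expected a stack of 2-D planes, got shape {planes.shape}")
    # accept channel-last layout (H, W, C) for small channel counts
    if planes.shape[0] > 8 and planes.shape[-1] <= 8:
        planes = np.moveaxis(planes, -1, 0)
    for key in ("dystrophin", "spectrin"):
        if key not in channel_map:
            raise FormatError(f"channel_map must assign a plane for '{key}'")
        if not (0 <= channel_map[key] < planes.shape[0]):
            raise FormatError(
                f"channel_map['{key}'] = {channel_map[key]} but file has "
                f"{planes.shape[0]} plane(s)"
            )
    meta = dict(meta or {})
    dys = planes[channel_map["dystrophin"]].astype(np.float64)
    spec = planes[channel_map["spectrin"]].astype(np.float64)
    for name, chan in (("dystrophin", dys), ("spectrin", spec)):
        if chan.min() < 0 or chan.max() > MAX_INTENSITY:
            raise ValidationError(
                f"{name} plane exceeds the 12-bit range [0, 4095] "
                f"(observed max {chan.max():.0f})"
            )
    return SectionImage(dystrophin=dys, spectrin=spec, pixel_size=pixel_size, **meta)


def write_section_image(image: SectionImage, path: str | Path) -> None:
    """Write the two channels as a 2-plane 16-bit TIFF (dystrophin first)."""
    stack = np.stack(
        [
            np.round(image.dystrophin).astype(np.uint16),
            np.round(image.spectrin).astype(np.uint16),
        ]
    )
    tifffile.imwrite(Path(path), stack)


#: Fixed column order of the per-fiber CSV table.
FIBER_TABLE_COLUMNS = [
    "biopsy_id",
    "section_id",
    "image_id",
    "fiber_id",
    "dys_mean",
    "dys_min",
    "dys_max",
    "dys_q90",
    "dys_q90_mean",
    "spec_mean",
    "csa_um2",
    "membrane_thickness_um",
    "n_membrane_pixels",
]


def write_fiber_table(metrics: Sequence, path: str | Path) -> pd.DataFrame:
    """Write per-fiber metrics as CSV (one row per fiber, fixed column order).

    Extra quantile levels beyond Q90 appear as ``dys_q<level>`` columns
    after the fixed block.  An empty collection yields a header-only file.
    Returns the frame that was written.
    """
    rows = [m.to_row() if hasattr(m, "to_row") else dict(m) for m in metrics]
    frame = pd.DataFrame(rows)
    extra = [c for c in frame.columns if c not in FIBER_TABLE_COLUMNS]
    cols = FIBER_TABLE_COLUMNS + sorted(extra)
    frame = frame.reindex(columns=cols)
    frame.to_csv(path, index=False, float_format="%.10g")
    return frame


def read_fiber_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_run_manifest(path: str | Path, manifest: Mapping[str, object]) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
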