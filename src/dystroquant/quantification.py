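"""Per-fiber membrane intensity statistics and morphometry.

The measurand is the dystrophin signal inside the spectrin-defined
sarcolemmal mask of each fiber.  Quantiles follow the nearest-rank
(order-statistic) convention: the Q-level value is the cut-off between
the lowest ``level`` fraction of membrane pixels and the rest, and the
Q90-mean is the arithmetic mean of the brightest ``ceil(0.1 n)`` pixels.
No interpolation is used, so results are bit-exactly reproducible.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
from skimage import measure

from .io import AnalysisConfig, SectionImage
from .segmentation import Fiber


@dataclasses.dataclass
class IntensityStats:
    mean: float
    min: float
    max: float
    quantiles: dict[float, float]
    q90_mean: float


@dataclasses.dataclass
class FiberMetrics:
    """Intensity statistics and morphometry of one QC-passing fiber."""

    fiber_id: int
    biopsy_id: str
    section_id: str
    image_id: str
    dys_mean: float
    dys_min: float
    dys_max: float
    dys_quantiles: dict[float, float]
    dys_q90_mean: float
    spec_mean: float
    csa_um2: float
    membrane_thickness_um: float
    n_membrane_pixels: int
    degenerate: bool = False

    @property
    def dys_q90(self) -> float:
        return self.dys_quantiles[0.9]

    def to_row(self) -> dict:
        row = {
            "biopsy_id": self.biopsy_id,
            "section_id": self.section_id,
            "image_id": self.image_id,
            "fiber_id": self.fiber_id,
            "dys_mean": self.dys_mean,
            "dys_min": self.dys_min,
            "dys_max": self.dys_max,
            "dys_q90": self.dys_q90,
            "dys_q90_mean": self.dys_q90_mean,
            "spec_mean": self.spec_mean,
            "csa_um2": self.csa_um2,
            "membrane_thickness_um": self.membrane_thickness_um,
            "n_membrane_pixels": self.n_membrane_pixels,
        }
        for level, value in sorted(self.dys_quantiles.items()):
            if not math.isclose(level, 0.9):
                row[f"dys_q{int(round(level * 100)):02d}"] = value
        return row


def nearest_rank_quantile(values: np.ndarray, level: float) -> float:
    """Order-statistic quantile: the ceil(level*n)-th smallest value."""
    n = len(values)
    k = max(1, math.ceil(level * n))
    return float(np.partition(values, k - 1)[k - 1])


def membrane_intensity_stats(
    membrane_idx: tuple[np.ndarray, np.ndarray] | np.ndarray,
    channel: np.ndarray,
    levels: Sequence[float] = (0.1, 0.25, 0.5, 0.75, 0.9),
) -> IntensityStats:
    """Intensity statistics over a fiber's membrane pixel set.

    ``membrane_idx`` may be an ``(rows, cols)`` index pair or a boolean
    mask.  The mean is the plain arithmetic mean over mask pixels; the
    Q90-mean averages the top ``ceil(0.1 n)`` pixels by intensity.
    """
    channel = np.asarray(channel, dtype=np.float64)
    if isinstance(membrane_idx, np.ndarray) and membrane_idx.dtype == bool:
        values = channel[membrane_idx]
    else:
        values = channel[membrane_idx]
    n = len(values)
    if n == 0:
        raise ValueError("empty membrane mask: quantify only qc_pass fibers")
    sorted_values = np.sort(values)
    quantiles = {
        float(level): float(sorted_values[max(1, math.ceil(level * n)) - 1])
        for level in levels
    }
    m = math.ceil(0.1 * n)
    return IntensityStats(
        mean=float(values.mean()),
        min=float(sorted_values[0]),
        max=float(sorted_values[-1]),
        quantiles=quantiles,
        q90_mean=float(sorted_values[n - m:].mean()),
    )


def fiber_morphometry(fiber: Fiber, pixel_size: float,
                      shape: tuple[int, int] | None = None) -> tuple[float, float, bool]:
    """Cross-sectional area (um^2) and mean membrane thickness (um).

    CSA counts membrane plus cytoplasm pixels.  Thickness is estimated as
    membrane area divided by the length of the membrane's inner contour
    (the cytoplasm perimeter), a deterministic area/perimeter ratio that
    approximates the mean band width.  For degenerate fibers without
    cytoplasm the membrane's own perimeter/2 stands in for the contour
    and the result is flagged.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    n_mem, n_cyt = fiber.n_membrane, fiber.n_cytoplasm
    csa_um2 = (n_mem + n_cyt) * pixel_size**2
    if shape is None:
        rows = np.concatenate([fiber.membrane_idx[0], fiber.cytoplasm_idx[0]])
        cols = np.concatenate([fiber.membrane_idx[1], fiber.cytoplasm_idx[1]])
        shape = (int(rows.max()) + 2, int(cols.max()) + 2)
    degenerate = n_cyt == 0
    if degenerate:
        contour_px = measure.perimeter(fiber.membrane_mask(shape)) / 2.0
    else:
        contour_px = measure.perimeter(fiber.cytoplasm_mask(shape))
    if contour_px <= 0:
        contour_px = max(1.0, 4.0 * math.sqrt(max(n_cyt, n_mem)))
    thickness_um = n_mem * pixel_size / contour_px
    return csa_um2, thickness_um, degenerate


def quantify_image(
    image: SectionImage,
    fibers: Iterable[Fiber],
    config: AnalysisConfig,
) -> list[FiberMetrics]:
    """Compute FiberMetrics for every qc_pass fiber of one image."""
    h, w = image.shape
    metrics: list[FiberMetrics] = []
    for fiber in fibers:
        if not fiber.qc_pass:
            continue
        for rr, cc in (fiber.membrane_idx, fiber.cytoplasm_idx):
            if len(rr) and (rr.max() >= h or cc.max() >= w):
                raise ValueError(
                    f"fiber {fiber.fiber_id} indices exceed image shape {image.shape}: "
                    "fibers were not segmented from this image"
                )
        dys = membrane_intensity_stats(
            fiber.membrane_idx, image.dystrophin, config.quantile_levels
        )
        spec = membrane_intensity_stats(fiber.membrane_idx, image.spectrin, (0.9,))
        csa, thickness, degenerate = fiber_morphometry(
            fiber, image.pixel_size, image.shape
        )
        metrics.append(
            FiberMetrics(
                fiber_id=fiber.fiber_id,
                biopsy_id=image.biopsy_id,
                section_id=image.section_id,
                image_id=image.image_id,
                dys_mean=dys.mean,
                dys_min=dys.min,
                dys_max=dys.max,
                dys_quantiles=dys.quantiles,
                dys_q90_mean=dys.q90_mean,
                spec_mean=spec.mean,
                csa_um2=csa,
                membrane_thickness_um=thickness,
                n_membrane_pixels=fiber.n_membrane,
                degenerate=degenerate,
            )
        )
    return metrics
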