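"""Spectrin-driven muscle fiber segmentation.

Muscle cross-sections stained for spectrin show each fiber as a bright
sarcolemmal ring around a dim interior.  Segmentation therefore proceeds
from the spectrin channel alone:

1. smooth the spectrin channel with a Gaussian at a configurable scale;
2. threshold a *relative* (percentile-anchored) membrane-ness level to get
   the candidate membrane band, so the result is invariant to global
   detector gain;
3. take connected low-intensity basins as fiber interiors, rejecting
   components that are too small, implausibly large (fibrotic/empty areas,
   the background sea), insufficiently enclosed by membrane signal, or
   that occupy most of the image border;
4. assign every membrane-band pixel to the fiber whose interior is
   nearest (Euclidean distance transform), capped at the maximum
   predicted membrane thickness, so touching membranes of adjacent fibers
   are split into disjoint per-fiber bands.

Regions use 4-connectivity; boundary/contour tests use 8-connectivity.
All steps are deterministic for a fixed input and configuration.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from .io import AnalysisConfig, SectionImage, ValidationError

QC_OK = "ok"
QC_BORDER = "border"
QC_TOO_SMALL = "too_small"
QC_INCOMPLETE_MEMBRANE = "incomplete_membrane"
QC_NO_MEMBRANE = "no_membrane"


@dataclasses.dataclass
class FiberLabelMap:
    """Per-pixel fiber assignment (0 = background / non-fiber).

    ``labels`` holds contiguous integer labels ``1..n_fibers`` covering
    each fiber's interior plus its share of the membrane band.
    ``membrane_band`` is the thresholded spectrin-positive band the labels
    were built from; it is carried along so the membrane/cytoplasm split
    reuses exactly the same band.
    """

    labels: np.ndarray
    n_fibers: int
    membrane_band: np.ndarray
    pixel_size: float


@dataclasses.dataclass
class Fiber:
    """One segmented fiber: disjoint membrane and cytoplasm pixel sets.

    Pixel sets are stored as ``(rows, cols)`` index arrays into the image
    grid.  ``membrane_idx`` is the sarcolemmal band (spectrin-positive),
    ``cytoplasm_idx`` the enclosed interior; their union is the fiber's
    labeled region.
    """

    fiber_id: int
    membrane_idx: tuple[np.ndarray, np.ndarray]
    cytoplasm_idx: tuple[np.ndarray, np.ndarray]
    touches_border: bool = False
    qc_pass: bool = True
    qc_reason: str = QC_OK

    @property
    def n_membrane(self) -> int:
        return len(self.membrane_idx[0])

    @property
    def n_cytoplasm(self) -> int:
        return len(self.cytoplasm_idx[0])

    @property
    def area_px(self) -> int:
        return self.n_membrane + self.n_cytoplasm

    def membrane_mask(self, shape: tuple[int, int]) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        mask[self.membrane_idx] = True
        return mask

    def cytoplasm_mask(self, shape: tuple[int, int]) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        mask[self.cytoplasm_idx] = True
        return mask


def membrane_band_mask(spectrin: np.ndarray, config: AnalysisConfig,
                       pixel_size: float) -> np.ndarray:
    """Threshold the smoothed spectrin channel into a membrane-candidate band.

    Both threshold methods are relative to the image's own intensity
    distribution (Otsu on the smoothed histogram, or a point between two
    percentiles), so multiplying the channel by any positive gain leaves
    the band unchanged.
    """
    sigma_px = config.smoothing_sigma_um / pixel_size
    smoothed = ndi.gaussian_filter(spectrin, sigma_px) if sigma_px > 0 else spectrin
    lo = float(smoothed.min())
    hi = float(smoothed.max())
    if hi <= lo:  # flat image: no ridge structure, no membrane
        return np.zeros(spectrin.shape, dtype=bool)
    if config.ridge_threshold_method == "otsu":
        return smoothed > _exact_otsu(smoothed)
    elif config.ridge_threshold_method == "percentile":
        p_lo = np.percentile(smoothed, config.ridge_percentile_low)
        p_hi = np.percentile(smoothed, config.ridge_percentile_high)
        if p_hi <= p_lo:
            return np.zeros(spectrin.shape, dtype=bool)
        threshold = p_lo + config.ridge_threshold_fraction * (p_hi - p_lo)
        return smoothed >= threshold
    raise ValueError(
        f"unknown ridge_threshold_method '{config.ridge_threshold_method}'"
    )


def _exact_otsu(values: np.ndarray) -> float:
    """Otsu threshold maximizing between-class variance over the exact
    unique-value histogram (no binning), returned as the midpoint between
    the two classes so that ``values > threshold`` splits unambiguously.
    Binned implementations can misclassify a value sitting at the optimal
    cut when the histogram is spiky (few distinct levels).
    """
    vals, counts = np.unique(values, return_counts=True)
    if len(vals) < 2:
        return float(vals[-1])
    w = counts.astype(np.float64) / counts.sum()
    omega = np.cumsum(w)[:-1]
    mu = np.cumsum(w * vals)[:-1]
    mu_t = float((w * vals).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    k = int(np.nanargmax(sigma_b))
    return float(0.5 * (vals[k] + vals[k + 1]))


def _border_pixel_share(component_mask: np.ndarray) -> float:
    edges = np.concatenate(
        [component_mask[0, :], component_mask[-1, :],
         component_mask[1:-1, 0], component_mask[1:-1, -1]]
    )
    return float(edges.mean())


def _enclosure_fraction(component_mask: np.ndarray, band: np.ndarray) -> float:
    """Fraction of a component's outer contour lying on the membrane band."""
    ring = ndi.binary_dilation(component_mask, structure=np.ones((3, 3), bool))
    ring &= ~component_mask
    n_ring = int(ring.sum())
    if n_ring == 0:
        return 0.0
    return float((ring & band).sum()) / n_ring


def segment_fibers(image: SectionImage, config: AnalysisConfig) -> FiberLabelMap:
    """Identify individual muscle fibers from the spectrin channel.

    Returns a label map in which each fiber is one 4-connected region
    (interior plus assigned membrane share); background, fibrotic/empty
    areas and the extracellular sea receive label 0.  An image with no
    spectrin structure yields ``n_fibers = 0``.
    """
    spectrin = image.spectrin
    if not np.all(np.isfinite(spectrin)):
        raise ValidationError("non-finite values in spectrin channel")
    ps = image.pixel_size
    band = membrane_band_mask(spectrin, config, ps)

    interiors = measure.label(~band, connectivity=1)
    n_raw = int(interiors.max())
    if n_raw == 0:
        return FiberLabelMap(np.zeros(spectrin.shape, np.int32), 0, band, ps)

    seed_min_px = config.seed_min_area_um2 / ps**2
    max_area_px = config.max_fiber_area_um2 / ps**2
    areas = np.bincount(interiors.ravel(), minlength=n_raw + 1)

    keep: list[int] = []
    for k in range(1, n_raw + 1):
        if areas[k] < seed_min_px or areas[k] > max_area_px:
            continue
        comp = interiors == k
        if _border_pixel_share(comp) > 0.5:
            continue  # dominates the image border: background sea
        if _enclosure_fraction(comp, band) < config.enclosure_min_fraction:
            continue  # not ringed by membrane signal
        keep.append(k)

    if not keep:
        return FiberLabelMap(np.zeros(spectrin.shape, np.int32), 0, band, ps)

    # relabel survivors 1..n in scan order (measure.label is scan-ordered)
    remap = np.zeros(n_raw + 1, dtype=np.int32)
    for new, old in enumerate(keep, start=1):
        remap[old] = new
    interior_labels = remap[interiors]

    # assign membrane-band pixels to the nearest accepted interior,
    # capped at the maximum predicted membrane thickness
    cap_px = config.membrane_max_thickness_um / ps
    dist, (nr, nc) = ndi.distance_transform_edt(
        interior_labels == 0, return_indices=True
    )
    labels = interior_labels.copy()
    assignable = band & (interior_labels == 0) & (dist <= cap_px)
    labels[assignable] = interior_labels[nr[assignable], nc[assignable]]

    # enforce 4-connectivity: drop membrane crumbs disconnected from
    # their fiber's interior
    cc = measure.label(labels, connectivity=1, background=0)
    has_interior = np.zeros(cc.max() + 1, dtype=bool)
    interior_cc = cc[interior_labels > 0]
    has_interior[np.unique(interior_cc)] = True
    labels[~has_interior[cc]] = 0

    return FiberLabelMap(labels, len(keep), band, ps)


def split_touching_membranes(
    label_map: FiberLabelMap, spectrin: np.ndarray, config: AnalysisConfig
) -> list[Fiber]:
    """Partition each fiber's region into membrane and cytoplasm pixel sets.

    Every spectrin-positive band pixel inside a labeled region belongs to
    exactly that fiber's membrane; the remainder of the region is
    cytoplasm.  Globally, no membrane pixel is shared between fibers and
    none is dropped (the label map already resolved touching membranes by
    nearest-interior assignment with the thickness cap).
    """
    if config.membrane_max_thickness_um <= 0:
        raise ValueError("membrane_max_thickness_um must be > 0")
    labels = label_map.labels
    band = label_map.membrane_band
    h, w = labels.shape
    fibers: list[Fiber] = []
    slices = ndi.find_objects(labels, max_label=label_map.n_fibers)
    for fid in range(1, label_map.n_fibers + 1):
        sl = slices[fid - 1]
        if sl is None:
            continue
        region_local = labels[sl] == fid
        mem_local = region_local & band[sl]
        cyt_local = region_local & ~band[sl]
        off = (sl[0].start, sl[1].start)
        mr, mc = np.nonzero(mem_local)
        cr, cc = np.nonzero(cyt_local)
        rr = np.concatenate([mr, cr]) + off[0]
        rc = np.concatenate([mc, cc]) + off[1]
        touches = bool(
            (rr == 0).any() or (rr == h - 1).any()
            or (rc == 0).any() or (rc == w - 1).any()
        )
        fibers.append(
            Fiber(
                fiber_id=fid,
                membrane_idx=(mr + off[0], mc + off[1]),
                cytoplasm_idx=(cr + off[0], cc + off[1]),
                touches_border=touches,
            )
        )
    return fibers


def _membrane_coverage_fraction(fiber: Fiber, shape: tuple[int, int]) -> float:
    """Fraction of the cytoplasm's outer contour backed by membrane pixels."""
    if fiber.n_cytoplasm == 0:
        return 0.0
    cyt = fiber.cytoplasm_mask(shape)
    mem = fiber.membrane_mask(shape)
    ring = ndi.binary_dilation(cyt, structure=np.ones((3, 3), bool)) & ~cyt
    n_ring = int(ring.sum())
    if n_ring == 0:
        return 0.0
    return float((ring & mem).sum()) / n_ring


def qc_filter(
    fibers: list[Fiber], image: SectionImage, config: AnalysisConfig
) -> list[Fiber]:
    """Flag fibers failing quality control; nothing is deleted.

    Reasons, in order of precedence: clipped by the image border, area
    below ``min_fiber_area_um2``, no membrane pixels at all, or a membrane
    covering less than ``membrane_min_perimeter_fraction`` of the fiber
    perimeter (incomplete ring).  Downstream code filters on ``qc_pass``.
    """
    shape = image.shape
    min_area_px = config.min_fiber_area_um2 / image.pixel_size**2
    for fiber in fibers:
        if fiber.touches_border:
            fiber.qc_pass, fiber.qc_reason = False, QC_BORDER
        elif fiber.area_px < min_area_px:
            fiber.qc_pass, fiber.qc_reason = False, QC_TOO_SMALL
        elif fiber.n_membrane == 0:
            fiber.qc_pass, fiber.qc_reason = False, QC_NO_MEMBRANE
        elif _membrane_coverage_fraction(fiber, shape) < config.membrane_min_perimeter_fraction:
            fiber.qc_pass, fiber.qc_reason = False, QC_INCOMPLETE_MEMBRANE
        else:
            fiber.qc_pass, fiber.qc_reason = True, QC_OK
    return fibers


def segment_image(image: SectionImage, config: AnalysisConfig) -> list[Fiber]:
    """Convenience: segment, split membranes and QC-flag in one call."""
    label_map = segment_fibers(image, config)
    fibers = split_touching_membranes(label_map, image.spectrin, config)
    return qc_filter(fibers, image, config)
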