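"""Pore-size distributions from SEM-style micrographs.

Pores image dark on a bright background.  Each image is binarized
(Otsu threshold by default), 8-connected pore components are labeled,
and each pore's size is its equivalent circular diameter
d = 2·√(A/π).  Micrographs can contain large pores with smaller pores
nested inside; a second, darker binarization pass detects those and the
two detection sets are merged.  Per-sample distributions aggregate the
histograms of many images (30 in the standard protocol).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import filters, measure

from .errors import DataError

#: default bin edges (µm): sub-0.5, 0.5–1.0, 1.0–5.0 and larger
DEFAULT_BIN_EDGES = (0.0, 0.5, 1.0, 5.0, np.inf)

#: default analyzed field of view (µm) used to infer the pixel size
DEFAULT_FIELD_UM = 20.0


@dataclass
class PoreHistogram:
    bin_edges: np.ndarray       # µm
    counts: np.ndarray
    diameters: np.ndarray | None = None    # µm, individual pores

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, float)
        self.counts = np.asarray(self.counts, int)
        if len(self.counts) != len(self.bin_edges) - 1:
            raise DataError("counts/bin_edges length mismatch")
        if np.any(self.counts < 0):
            raise DataError("negative bin count")

    @property
    def total_pores(self) -> int:
        return int(self.counts.sum())

    @property
    def fractions(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts, float)
        return self.counts / total


def equivalent_diameter(area_px: float, pixel_size_um: float) -> float:
    """Equivalent circular diameter, 2·√(A/π), in µm."""
    return 2.0 * np.sqrt(area_px * pixel_size_um ** 2 / np.pi)


def _component_diameters(mask: np.ndarray, pixel_size_um: float,
                         min_area_px: int) -> list[float]:
    labels = measure.label(mask, connectivity=2)
    return [equivalent_diameter(r.area, pixel_size_um)
            for r in measure.regionprops(labels) if r.area >= min_area_px]


def pore_histogram_from_image(image: np.ndarray,
                              pixel_size_um: float | None = None,
                              bin_edges=DEFAULT_BIN_EDGES,
                              threshold: float | None = None,
                              two_pass: bool = True,
                              min_area_px: int = 4) -> PoreHistogram:
    """Binarize a grayscale micrograph and histogram pore diameters.

    ``pixel_size_um`` defaults to a 20 µm field of view divided by the
    image width.  ``threshold`` overrides the automatic Otsu threshold.
    With ``two_pass`` a second, darker threshold inside detected pores
    recovers pores nested within larger ones; both detection sets are
    merged.
    """
    img = np.asarray(image, float)
    if img.ndim != 2:
        raise DataError("expected a single-channel grayscale image")
    if pixel_size_um is None:
        pixel_size_um = DEFAULT_FIELD_UM / img.shape[1]
    bin_edges = np.asarray(bin_edges, float)

    if img.max() == img.min():
        warnings.warn("blank image: no pores detected", stacklevel=2)
        return PoreHistogram(bin_edges=bin_edges,
                             counts=np.zeros(len(bin_edges) - 1, int),
                             diameters=np.zeros(0))
    thr = filters.threshold_otsu(img) if threshold is None else threshold
    mask = img < thr
    if not mask.any():
        warnings.warn("no pixels below threshold: no pores detected",
                      stacklevel=2)
        return PoreHistogram(bin_edges=bin_edges,
                             counts=np.zeros(len(bin_edges) - 1, int),
                             diameters=np.zeros(0))
    diameters = _component_diameters(mask, pixel_size_um, min_area_px)

    if two_pass:
        inside = img[mask]
        # only run the darker pass if the pore interior is genuinely
        # bimodal (nested pores), not merely noisy: demand a mode
        # separation of >3 within-class standard deviations
        if inside.size > 2 * min_area_px and inside.max() > inside.min():
            thr2 = filters.threshold_otsu(inside)
            lo = inside[inside < thr2]
            hi = inside[inside >= thr2]
            if (len(lo) >= min_area_px and len(hi) >= min_area_px
                    and thr2 < thr):
                spread = max(lo.std(), hi.std(), 1e-9)
                if hi.mean() - lo.mean() > 3.0 * spread:
                    mask2 = img < thr2
                    if mask2.any() and mask2.sum() < mask.sum():
                        diameters += _component_diameters(
                            mask2, pixel_size_um, min_area_px)
    diameters = np.sort(np.asarray(diameters))
    counts, _ = np.histogram(diameters, bins=bin_edges)
    return PoreHistogram(bin_edges=bin_edges, counts=counts,
                         diameters=diameters)


def aggregate_histograms(histograms: list[PoreHistogram]) -> PoreHistogram:
    """Element-wise count sum over images of one sample."""
    if not histograms:
        raise DataError("nothing to aggregate")
    edges = histograms[0].bin_edges
    for h in histograms[1:]:
        if len(h.bin_edges) != len(edges) or not np.allclose(
                np.nan_to_num(h.bin_edges, posinf=1e300),
                np.nan_to_num(edges, posinf=1e300)):
            raise DataError("histograms have mismatched bin edges")
    counts = np.sum([h.counts for h in histograms], axis=0)
    diam = [h.diameters for h in histograms if h.diameters is not None]
    diameters = np.sort(np.concatenate(diam)) if diam else None
    return PoreHistogram(bin_edges=edges, counts=counts, diameters=diameters)
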