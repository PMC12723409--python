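"""Axon/myelin morphometry from labeled electron-microscopy masks.

The input is a 2D integer mask with classes background/axon/myelin
(:class:`~axonsf.protocol.LabelMask`).  The processing chain is

1. :func:`extract_axon_instances` — connected-component analysis of the axon
   class (8-connectivity, holes filled), with surrounding myelin assigned to
   the nearest axon so that the shared myelin of adjacent fibers is split.
2. :func:`filter_axon_instances` — the exclusion rules: unmyelinated axons,
   orphan myelin, blobs overlapping the 4-pixel image border, insufficient
   myelin perimeter coverage, excessive eccentricity, sub-resolution blobs.
   Thresholds differ between conventionally embedded (epon) and
   cryo-fixed (cryo) material.
3. :func:`measure_axon` — per-axon geometry from moment-based ellipse fits:
   inner diameter is the minor axis of the ellipse fitted to the axon pixels
   (so obliquely cut axons are not overestimated), outer diameter the minor
   axis of the axon+myelin blob; the g-ratio is their ratio.

The distribution summaries (:func:`kde_mode`, :func:`distribution_stats`)
also serve the dMRI diameter maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.stats import gaussian_kde
from skimage.measure import regionprops

from .protocol import AXON, MYELIN, LabelMask

__all__ = [
    "AxonCandidate",
    "AxonRecord",
    "DistributionStats",
    "FILTER_THRESHOLDS",
    "BORDER_PX",
    "MIN_AREA_PX",
    "extract_axon_instances",
    "filter_axon_instances",
    "measure_axon",
    "kde_mode",
    "distribution_stats",
]

#: (minimum myelin perimeter coverage, maximum eccentricity) per preparation.
FILTER_THRESHOLDS = {
    "epon": (0.95, 0.92),
    "cryo": (0.85, 0.975),
}

#: Blobs overlapping this many pixels from the image edge are excluded.
BORDER_PX = 4

#: Minimum axon area (px) for a meaningful moment ellipse.
MIN_AREA_PX = 10

_EIGHT = np.ones((3, 3), dtype=bool)


class EmptyDistributionError(ValueError):
    """No values survive filtering."""


@dataclass
class AxonCandidate:
    """One candidate blob: an axon component plus its assigned myelin.

    ``axon_rc`` / ``myelin_rc`` are (rows, cols) index arrays into the source
    mask.  Orphan myelin (a myelin component adjacent to no axon) appears as
    a candidate with empty ``axon_rc``.
    """

    label: int
    axon_rc: tuple
    myelin_rc: tuple
    image_shape: tuple

    @property
    def area_px(self):
        return len(self.axon_rc[0])

    @property
    def has_axon(self):
        return len(self.axon_rc[0]) > 0

    @property
    def has_myelin(self):
        return len(self.myelin_rc[0]) > 0

    def touches_border(self, border=BORDER_PX):
        """True if any axon pixel lies within ``border`` px of the image edge."""
        if not self.has_axon:
            rr, cc = self.myelin_rc
        else:
            rr, cc = self.axon_rc
        h, w = self.image_shape
        return bool(
            (rr < border).any() or (rr >= h - border).any()
            or (cc < border).any() or (cc >= w - border).any()
        )


@dataclass
class AxonRecord:
    """Morphometry of one accepted axon (all lengths in µm)."""

    inner_diameter: float
    outer_diameter: float
    myelin_thickness: float
    g: float
    eccentricity: float
    myelin_coverage: float
    touches_border: bool
    area_px: int
    centroid_px: tuple = (0.0, 0.0)


@dataclass
class DistributionStats:
    """Summary of a diameter (or g-ratio) distribution, µm."""

    n: int
    mean: float
    sd: float
    mode: float
    p90: float
    d_w: float | None = None

    def as_dict(self):
        return {
            "n": self.n, "mean": self.mean, "sd": self.sd,
            "mode": self.mode, "p90": self.p90, "d_w": self.d_w,
        }


def extract_axon_instances(mask: LabelMask):
    """Split a label mask into candidate myelinated-axon blobs.

    Axon components are labeled with 8-connectivity after hole filling.
    Every myelin pixel is assigned to the axon component whose pixels are
    nearest (Euclidean distance), which separates the shared myelin of
    adjacent fibers along the equidistance line.  Myelin components that
    touch no axon at all become orphan candidates (excluded downstream).
    """
    axon = ndimage.binary_fill_holes(mask.classes == AXON)
    myelin = (mask.classes == MYELIN) & ~axon
    axon_labels, n_axons = ndimage.label(axon, structure=_EIGHT)

    candidates = []
    if n_axons > 0:
        # nearest-axon pixel for every pixel of the image
        _, (ir, ic) = ndimage.distance_transform_edt(
            axon_labels == 0, return_indices=True
        )
        myelin_owner = np.zeros_like(axon_labels)
        myelin_owner[myelin] = axon_labels[ir[myelin], ic[myelin]]
        # myelin components with no axon anywhere near belong to no fiber:
        # keep only myelin whose component touches its owner axon
        myelin_cc, n_mcc = ndimage.label(myelin, structure=_EIGHT)
        touching = np.zeros(n_mcc + 1, dtype=bool)
        dil = ndimage.binary_dilation(axon, structure=_EIGHT)
        touching_ids = np.unique(myelin_cc[myelin & dil])
        touching[touching_ids] = True
        orphan = myelin & ~touching[myelin_cc]
        myelin_owner[orphan] = 0

        for lab in range(1, n_axons + 1):
            a_rc = np.nonzero(axon_labels == lab)
            m_rc = np.nonzero(myelin_owner == lab)
            candidates.append(AxonCandidate(lab, a_rc, m_rc, mask.classes.shape))

        if orphan.any():
            orphan_cc, n_occ = ndimage.label(orphan, structure=_EIGHT)
            for lab in range(1, n_occ + 1):
                m_rc = np.nonzero(orphan_cc == lab)
                candidates.append(
                    AxonCandidate(n_axons + lab, (np.array([], int),) * 2, m_rc,
                                  mask.classes.shape)
                )
    else:
        myelin_cc, n_mcc = ndimage.label(myelin, structure=_EIGHT)
        for lab in range(1, n_mcc + 1):
            m_rc = np.nonzero(myelin_cc == lab)
            candidates.append(
                AxonCandidate(lab, (np.array([], int),) * 2, m_rc, mask.classes.shape)
            )
    return candidates


def _local_patch(rc_list, shape):
    """Boolean patches for a candidate, cropped to a common bounding box."""
    rr = np.concatenate([rc[0] for rc in rc_list if len(rc[0])])
    cc = np.concatenate([rc[1] for rc in rc_list if len(rc[1])])
    r0, r1 = rr.min(), rr.max() + 1
    c0, c1 = cc.min(), cc.max() + 1
    patches = []
    for rc in rc_list:
        p = np.zeros((r1 - r0 + 2, c1 - c0 + 2), dtype=bool)  # 1-px pad
        if len(rc[0]):
            p[rc[0] - r0 + 1, rc[1] - c0 + 1] = True
        patches.append(p)
    return patches, (r0 - 1, c0 - 1)


def _minor_axis_and_ecc(patch):
    """Minor-axis length (px) and eccentricity of the moment ellipse."""
    props = regionprops(patch.astype(np.uint8))
    if not props:
        return 0.0, 0.0, (0.0, 0.0)
    p = props[0]
    return p.axis_minor_length, p.eccentricity, p.centroid


def measure_axon(candidate: AxonCandidate, pixel_size):
    """Per-axon morphometry from moment-ellipse fits (lengths in µm).

    The inner ellipse is fitted to the axon pixels, the outer ellipse to the
    hole-filled union of axon and myelin; diameters are the ellipse minor
    axes scaled by the pixel size.  Myelin coverage is the fraction of the
    axon's outer-boundary pixels with at least one myelin pixel in their
    8-neighborhood.
    """
    (axon_p, myelin_p), offset = _local_patch(
        [candidate.axon_rc, candidate.myelin_rc], candidate.image_shape
    )
    inner_minor, ecc, centroid = _minor_axis_and_ecc(axon_p)
    outer = ndimage.binary_fill_holes(axon_p | myelin_p)
    outer_minor, _, _ = _minor_axis_and_ecc(outer)
    outer_minor = max(outer_minor, inner_minor)

    boundary = axon_p & ~ndimage.binary_erosion(axon_p, structure=_EIGHT)
    n_boundary = int(boundary.sum())
    if n_boundary and candidate.has_myelin:
        near_myelin = ndimage.binary_dilation(myelin_p, structure=_EIGHT)
        coverage = float((boundary & near_myelin).sum()) / n_boundary
    else:
        coverage = 0.0

    inner_d = inner_minor * pixel_size
    outer_d = outer_minor * pixel_size
    return AxonRecord(
        inner_diameter=inner_d,
        outer_diameter=outer_d,
        myelin_thickness=(outer_d - inner_d) / 2.0,
        g=inner_d / outer_d if outer_d > 0 else float("nan"),
        eccentricity=ecc,
        myelin_coverage=coverage,
        touches_border=candidate.touches_border(),
        area_px=candidate.area_px,
        centroid_px=(centroid[0] + offset[0], centroid[1] + offset[1]),
    )


def filter_axon_instances(candidates, preparation, pixel_size,
                          min_area_px=MIN_AREA_PX, border_px=BORDER_PX,
                          thresholds=None):
    """Apply the exclusion rules and measure the survivors.

    Returns ``(records, counts)`` where ``counts`` tallies every candidate by
    outcome: ``accepted`` plus one reason per exclusion (``no_axon``,
    ``no_myelin``, ``min_area``, ``border``, ``coverage``, ``eccentricity``).
    The tallies sum to ``len(candidates)``.
    """
    if thresholds is None:
        if preparation not in FILTER_THRESHOLDS:
            raise ValueError(f"unknown preparation {preparation!r}; expected "
                             f"{sorted(FILTER_THRESHOLDS)}")
        coverage_min, ecc_max = FILTER_THRESHOLDS[preparation]
    else:
        coverage_min, ecc_max = thresholds

    counts = {k: 0 for k in
              ("accepted", "no_axon", "no_myelin", "min_area", "border",
               "coverage", "eccentricity")}
    records = []
    for cand in candidates:
        if not cand.has_axon:
            counts["no_axon"] += 1
            continue
        if not cand.has_myelin:
            counts["no_myelin"] += 1
            continue
        if cand.area_px < min_area_px:
            counts["min_area"] += 1
            continue
        if cand.touches_border(border_px):
            counts["border"] += 1
            continue
        rec = measure_axon(cand, pixel_size)
        if rec.myelin_coverage < coverage_min:
            counts["coverage"] += 1
            continue
        if rec.eccentricity > ecc_max:
            counts["eccentricity"] += 1
            continue
        counts["accepted"] += 1
        records.append(rec)
    return records, counts


# ---------------------------------------------------------------------------
# Distribution summaries
# ---------------------------------------------------------------------------

def kde_mode(values, bandwidth="silverman", grid_points=512):
    """Mode of a distribution as the argmax of a Gaussian KDE.

    Silverman bandwidth by default; the argmax is taken on a ``grid_points``
    grid spanning [max(0, min − 3h), max + 3h] where h is the KDE bandwidth.
    Degenerate inputs (single or constant sample) return the value itself.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise EmptyDistributionError("cannot estimate a mode from no values")
    if values.size == 1 or np.ptp(values) == 0:
        return float(values.flat[0])
    kde = gaussian_kde(values, bw_method=bandwidth)
    h = kde.factor * values.std(ddof=1)
    lo = max(0.0, values.min() - 3 * h)
    hi = values.max() + 3 * h
    grid = np.linspace(lo, hi, grid_points)
    return float(grid[np.argmax(kde(grid))])


def distribution_stats(values, bandwidth="silverman", grid_points=512):
    """Mean, SD (ddof=1), KDE mode and interpolated 90th percentile."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise EmptyDistributionError("empty distribution")
    return DistributionStats(
        n=int(values.size),
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if values.size > 1 else 0.0,
        mode=kde_mode(values, bandwidth=bandwidth, grid_points=grid_points),
        p90=float(np.percentile(values, 90)),
    )
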