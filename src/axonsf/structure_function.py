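"""Shrinkage correction, MR-weighted diameter, and the conduction-time ↔
axon-diameter conversion.

Two algebraic relations tie the modalities together.  The measured relation

    CV = L / TCT                                             (pathway)

gives conduction velocity from tract length L (mm) and conduction time
TCT (ms); mm/ms is numerically m/s.  The structural relation for myelinated
CNS axons,

    CV = (5.5 / g) · d,

states that conduction velocity is proportional to the *outer* fiber
diameter with slope 5.5 m/s per µm; expressing it through the inner axon
diameter d (µm) introduces the g-ratio g = d_inner / d_outer.  Combining the
two converts in either direction: TCT = L·g/(5.5·d) and d = L·g/(5.5·TCT).

Dehydration during conventional resin embedding shrinks axons relative to
cryo-fixed material; the shrinkage factor on a distribution summary x is
(cryo_x − epon_x)·100/cryo_x, computed for the mode and the 90th percentile,
and the general factor is their average.  Correction divides measured
diameters by (1 − s/100), the exact inverse of that definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .morphometry import DistributionStats

__all__ = [
    "CV_SLOPE",
    "ShrinkageResult",
    "PathwayModel",
    "shrinkage_factor",
    "apply_shrinkage_correction",
    "mr_weighted_diameter",
    "conduction_velocity",
    "cv_from_diameter",
    "predict_diameter",
    "predict_tct",
]

#: Conduction-velocity slope: m/s per µm of outer fiber diameter.
CV_SLOPE = 5.5


@dataclass(frozen=True)
class ShrinkageResult:
    """Shrinkage factors in percent; ``s_general`` is the mean of the two."""

    s_mode: float
    s_p90: float

    @property
    def s_general(self):
        return 0.5 * (self.s_mode + self.s_p90)


@dataclass
class PathwayModel:
    """Structure–function state of one pathway.

    L in mm, TCT in ms, CV in m/s, d (inner axon diameter) in µm.  Any
    populated instance must satisfy CV·TCT = L and CV = (5.5/g)·d.
    """

    L: float | None = None
    TCT: float | None = None
    CV: float | None = None
    g: float | None = None
    d: float | None = None

    def validate(self, rtol=1e-6):
        if None not in (self.L, self.TCT, self.CV):
            if abs(self.CV * self.TCT - self.L) > rtol * abs(self.L):
                raise ValueError("CV·TCT != L")
        if None not in (self.CV, self.g, self.d):
            if abs(self.CV - (CV_SLOPE / self.g) * self.d) > rtol * abs(self.CV):
                raise ValueError("CV != (5.5/g)·d")
        return self

    @classmethod
    def from_measurements(cls, L, TCT, g):
        cv = conduction_velocity(L, TCT)
        return cls(L=L, TCT=TCT, CV=cv, g=g, d=predict_diameter(TCT, L, g)).validate()


def shrinkage_factor(epon: DistributionStats, cryo: DistributionStats):
    """Mode- and p90-based shrinkage of epon relative to cryo, percent."""
    if cryo.mode <= 0 or cryo.p90 <= 0:
        raise ValueError("cryo mode and p90 must be positive")
    s_mode = (cryo.mode - epon.mode) * 100.0 / cryo.mode
    s_p90 = (cryo.p90 - epon.p90) * 100.0 / cryo.p90
    return ShrinkageResult(s_mode=s_mode, s_p90=s_p90)


def apply_shrinkage_correction(diameters, s_percent, multiplicative=False):
    """Undo a shrinkage of ``s_percent`` on measured diameters.

    The default divides by (1 − s/100), the exact inverse of the shrinkage
    definition (shrinkage is expressed relative to the cryo reference).
    ``multiplicative=True`` instead multiplies by (1 + s/100), a convention
    some older reports use; the two differ at second order in s.
    """
    if not (0 <= s_percent < 100):
        raise ValueError("shrinkage percent must lie in [0, 100)")
    d = np.asarray(diameters, dtype=float)
    if multiplicative:
        out = d * (1.0 + s_percent / 100.0)
    else:
        out = d / (1.0 - s_percent / 100.0)
    return out if out.ndim else float(out)


def mr_weighted_diameter(diameters):
    """Tail-weighted effective diameter d_w = 2(⟨R⁶⟩/⟨R²⟩)^0.25, µm.

    This is the diameter an MRI voxel effectively reports in the wide-pulse
    limit, where the per-axon signal weight scales with R⁴ (volume × R²
    sensitivity); always ≥ the arithmetic mean, with equality only for a
    monodisperse sample.
    """
    d = np.asarray(diameters, dtype=float)
    if d.size == 0 or np.any(d <= 0):
        raise ValueError("diameters must be non-empty and positive")
    r = d / 2.0
    return float(2.0 * (np.mean(r**6) / np.mean(r**2)) ** 0.25)


def _require_positive(**kwargs):
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be positive, got {value}")


def _require_g(g):
    if not (0 < g < 1):
        raise ValueError(f"g-ratio must lie in (0, 1), got {g}")


def conduction_velocity(L, TCT):
    """CV = L/TCT in m/s, with L in mm and TCT in ms."""
    _require_positive(L=L, TCT=TCT)
    return L / TCT


def cv_from_diameter(d, g):
    """CV = (5.5/g)·d in m/s, with inner diameter d in µm."""
    _require_positive(d=d)
    _require_g(g)
    return (CV_SLOPE / g) * d


def predict_diameter(TCT, L, g):
    """Inner axon diameter (µm) implied by a conduction time: d = L·g/(5.5·TCT)."""
    _require_positive(TCT=TCT, L=L)
    _require_g(g)
    return L * g / (CV_SLOPE * TCT)


def predict_tct(d, L, g):
    """Conduction time (ms) implied by an inner diameter: TCT = L·g/(5.5·d)."""
    _require_positive(d=d, L=L)
    _require_g(g)
    return L * g / (CV_SLOPE * d)
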