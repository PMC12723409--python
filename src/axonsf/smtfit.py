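"""Per-voxel estimation of axon diameter from powder-averaged dMRI signals.

Pipeline per voxel: normalize by the voxel-wise mean of the b=0 images,
average the directional signals of each shell (the powder average), fit the
two free parameters (va, D⊥) of the spherical-mean model with the intrinsic
diffusivity D0 held fixed, then invert the monotone forward map
R ↦ D⊥(R) to obtain the cylinder diameter.  D0 comes either from
configuration or from a diffusion-tensor fit to the lower-b shell
(:func:`fit_dti_principal_diffusivity`).

Estimates below 0.1 µm are discarded from distribution summaries; voxels
whose D⊥ lands on the lower bound report a diameter of exactly zero and are
tracked as a separate state, mirroring the zero-diameter voxels seen in
high-b axon diameter maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, least_squares

from . import morphometry
from .cylinder import effective_Dperp, smt_powder_signal
from .protocol import B0_THRESHOLD_S_MM2, DWIDataset, PGSEProtocol

__all__ = [
    "PowderSignal",
    "SMTFitResult",
    "DiameterMap",
    "InvalidVoxelError",
    "FitError",
    "DISCARD_UM",
    "R_MAX_UM",
    "powder_average",
    "fit_dti_principal_diffusivity",
    "fit_smt",
    "diameter_from_Dperp",
    "fit_smt_volume",
    "roi_diameter_distribution",
]

#: Diameter estimates below this (µm) are discarded from summaries.
DISCARD_UM = 0.1

#: Upper end of the radius bracket used when inverting D⊥(R); estimates
#: requiring a larger radius are capped and flagged.
R_MAX_UM = 10.0

#: Powder-average values above this are treated as corrupt input.
SBAR_MAX = 1.5


class InvalidVoxelError(ValueError):
    """Voxel cannot be normalized or averaged (e.g. non-positive b0 mean)."""


class FitError(RuntimeError):
    """Model fit impossible (e.g. rank-deficient tensor design)."""


@dataclass
class PowderSignal:
    """Normalized spherical-mean signal per shell."""

    b_shells: np.ndarray    # s/mm²
    sbar: np.ndarray        # S̄/S0 per shell
    n_dirs: np.ndarray      # directions averaged per shell

    def __post_init__(self):
        self.b_shells = np.atleast_1d(np.asarray(self.b_shells, float))
        self.sbar = np.atleast_1d(np.asarray(self.sbar, float))
        self.n_dirs = np.atleast_1d(np.asarray(self.n_dirs, int))
        if not (len(self.b_shells) == len(self.sbar) == len(self.n_dirs)):
            raise ValueError("one sbar and direction count per shell")
        if np.any(self.sbar > SBAR_MAX) or np.any(self.sbar < 0):
            raise InvalidVoxelError(
                f"powder-average signal outside [0, {SBAR_MAX}] — corrupt voxel"
            )


@dataclass
class SMTFitResult:
    va: float
    Dperp: float            # µm²/ms
    D0_used: float          # µm²/ms
    diameter: float         # µm
    residual_norm: float
    converged: bool
    capped: bool = False


@dataclass
class DiameterMap:
    """Per-voxel diameter estimates with their bookkeeping states.

    ``state`` codes: 0 = valid estimate, 1 = zero-diameter (D⊥ at the lower
    bound), 2 = discarded (0 < d < 0.1 µm), 3 = invalid voxel / failed fit.
    """

    diameter: np.ndarray
    state: np.ndarray
    roi: np.ndarray

    OK, ZERO, DISCARDED, INVALID = 0, 1, 2, 3

    @classmethod
    def from_diameters(cls, diameters, roi=None):
        """Build a map from raw per-voxel estimates, deriving the states."""
        d = np.asarray(diameters, dtype=float)
        if roi is None:
            roi = np.ones_like(d, dtype=bool)
        state = np.where(
            d == 0.0, cls.ZERO, np.where(d < DISCARD_UM, cls.DISCARDED, cls.OK)
        ).astype(np.int8)
        state[np.isnan(d)] = cls.INVALID
        return cls(diameter=d, state=state, roi=np.asarray(roi, bool))


def powder_average(dataset: DWIDataset, voxel):
    """Powder average of one voxel: b0-normalize, then per-shell mean.

    Raises :class:`InvalidVoxelError` if the voxel-wise mean of the b=0
    images is not positive or a shell average is implausibly large.
    """
    sig = dataset.volume[tuple(voxel)]
    b0 = dataset.b0_mask
    if not b0.any():
        raise InvalidVoxelError("dataset has no b=0 measurements")
    s0 = sig[b0].mean()
    if s0 <= 0:
        raise InvalidVoxelError("non-positive b0 mean")
    shells = dataset.shell_bvalues()
    sbar, ndirs = [], []
    for b in shells:
        idx = dataset.shell_indices(b)
        sbar.append(sig[idx].mean() / s0)
        ndirs.append(len(idx))
    return PowderSignal(b_shells=shells, sbar=np.array(sbar), n_dirs=np.array(ndirs))


def fit_dti_principal_diffusivity(signals, bvecs, bvals):
    """Largest tensor eigenvalue from a log-linear DTI fit, µm²/ms.

    Parameters
    ----------
    signals : ndarray
        Shape (n_meas,) for a single voxel or (n_voxels, n_meas) for an ROI;
        the returned diffusivity is the principal eigenvalue averaged over
        ROI voxels.
    bvecs : ndarray, (n_meas, 3)
    bvals : ndarray, s/mm² (b0 rows identified as b < 50 s/mm²)
    """
    signals = np.atleast_2d(np.asarray(signals, float))
    bvecs = np.asarray(bvecs, float)
    bvals = np.asarray(bvals, float)
    dw = bvals >= B0_THRESHOLD_S_MM2
    # canonicalize antipodal directions before counting unique ones
    v = bvecs[dw].copy()
    flip = v[:, 0] < 0
    v[flip] *= -1
    n_unique = len(np.unique(np.round(v, 6), axis=0))
    if n_unique < 6:
        raise FitError(f"tensor fit needs >= 6 unique directions, got {n_unique}")
    gx, gy, gz = bvecs.T
    design = np.column_stack([
        np.ones_like(bvals),
        -bvals * gx * gx, -bvals * gy * gy, -bvals * gz * gz,
        -2 * bvals * gx * gy, -2 * bvals * gx * gz, -2 * bvals * gy * gz,
    ])
    if np.linalg.matrix_rank(design) < 7:
        raise FitError("rank-deficient tensor design matrix")
    eigmax = []
    for s in signals:
        if np.any(s <= 0):
            raise FitError("non-positive signal in tensor fit")
        coef, *_ = np.linalg.lstsq(design, np.log(s), rcond=None)
        dxx, dyy, dzz, dxy, dxz, dyz = coef[1:]
        tensor = np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])
        eigmax.append(np.linalg.eigvalsh(tensor)[-1])       # mm²/s
    return float(np.mean(eigmax) * 1e3)                     # µm²/ms


#: Multi-start grid for the bounded (va, D⊥) fit, as fractions of (1, D0).
_FIT_STARTS = ((0.3, 0.05), (0.6, 0.05), (0.9, 0.05), (0.5, 0.3), (0.8, 0.7))


def fit_smt(powder: PowderSignal, protocol: PGSEProtocol, D0,
            compute_diameter=True):
    """Bounded non-linear least squares for (va, D⊥) with D0 fixed.

    Best of a 5-point multi-start grid; the objective has a shallow valley
    at low D⊥ which single starts can miss.  Returns an
    :class:`SMTFitResult` whose diameter is obtained by inverting the
    forward map at the protocol's (δ, Δ).
    """
    if D0 <= 0:
        raise ValueError("D0 must be positive")
    if len(powder.b_shells) < 2:
        raise FitError("need at least two shells to separate va and Dperp")
    b, y = powder.b_shells, powder.sbar

    def residual(p):
        return smt_powder_signal(b, p[0], D0, p[1]) - y

    best = None
    converged = False
    for va0, f0 in _FIT_STARTS:
        res = least_squares(
            residual, x0=[va0, f0 * D0],
            bounds=([0.0, 0.0], [1.0, D0]),
            method="trf", xtol=1e-10, ftol=1e-10, gtol=1e-10,
        )
        converged = converged or res.status > 0
        if best is None or res.cost < best.cost:
            best = res
    va, Dperp = best.x
    d, capped = (0.0, False)
    if compute_diameter:
        d, capped = diameter_from_Dperp(
            Dperp, protocol, D0, full_output=True
        )
    return SMTFitResult(
        va=float(va), Dperp=float(Dperp), D0_used=float(D0),
        diameter=float(d), residual_norm=float(np.sqrt(2 * best.cost)),
        converged=bool(converged), capped=capped,
    )


def diameter_from_Dperp(Dperp, protocol: PGSEProtocol, D0, full_output=False):
    """Invert the monotone map R ↦ D⊥(R) and return the diameter 2R, µm.

    Uses bisection (Brent) on the GPD forward model at the protocol's shared
    (δ, Δ); gradient strength cancels and plays no role.  ``Dperp = 0``
    maps to 0.  Values above the forward map's supremum on R ∈ [0, 10] µm
    are capped at d = 20 µm and flagged.
    """
    if Dperp < 0 or Dperp > D0:
        raise ValueError("require 0 <= Dperp <= D0")
    if Dperp == 0:
        return (0.0, False) if full_output else 0.0

    def f(R):
        return effective_Dperp(R, protocol.delta, protocol.Delta, D0,
                               gamma=protocol.gamma) - Dperp

    if f(R_MAX_UM) < 0:
        return (2.0 * R_MAX_UM, True) if full_output else 2.0 * R_MAX_UM
    r = brentq(f, 1e-6, R_MAX_UM, xtol=1e-12, rtol=8.9e-16)
    d = 2.0 * r
    return (d, False) if full_output else d


def fit_smt_volume(dataset: DWIDataset, protocol: PGSEProtocol, D0, roi=None):
    """Fit every ROI voxel of a dataset and assemble a :class:`DiameterMap`."""
    shape = dataset.volume.shape[:3]
    if roi is None:
        roi = np.ones(shape, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    diameter = np.zeros(shape)
    state = np.full(shape, DiameterMap.INVALID, dtype=np.int8)
    for voxel in np.argwhere(roi):
        try:
            powder = powder_average(dataset, voxel)
            fit = fit_smt(powder, protocol, D0)
        except (InvalidVoxelError, FitError):
            continue
        if not fit.converged:
            continue
        v = tuple(voxel)
        diameter[v] = fit.diameter
        if fit.diameter == 0.0:
            state[v] = DiameterMap.ZERO
        elif fit.diameter < DISCARD_UM:
            state[v] = DiameterMap.DISCARDED
        else:
            state[v] = DiameterMap.OK
    return DiameterMap(diameter=diameter, state=state, roi=roi)


def roi_diameter_distribution(dmap: DiameterMap):
    """Distribution summary of an ROI's valid diameter estimates.

    Zero-diameter and discarded (< 0.1 µm) voxels are excluded from the
    statistics but reported in the returned counts.
    """
    in_roi = dmap.roi
    counts = {
        "n_roi": int(in_roi.sum()),
        "n_valid": int(((dmap.state == DiameterMap.OK) & in_roi).sum()),
        "n_zero": int(((dmap.state == DiameterMap.ZERO) & in_roi).sum()),
        "n_discarded": int(((dmap.state == DiameterMap.DISCARDED) & in_roi).sum()),
        "n_invalid": int(((dmap.state == DiameterMap.INVALID) & in_roi).sum()),
    }
    values = dmap.diameter[(dmap.state == DiameterMap.OK) & in_roi]
    if values.size == 0:
        raise morphometry.EmptyDistributionError(
            "all ROI voxels are zero, discarded or invalid"
        )
    stats = morphometry.distribution_stats(values)
    return stats, counts
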