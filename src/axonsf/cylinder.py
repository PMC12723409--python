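"""Forward signal model for diffusion inside axons modeled as cylinders.

Three layers, in the order the signal is built:

1. :func:`gpd_perpendicular_signal` — Gaussian-phase-distribution (GPD)
   attenuation of the PGSE signal perpendicular to an impermeable cylinder,
   a series over the roots of J1'.
2. :func:`effective_Dperp` — the apparent perpendicular diffusivity implied
   by that attenuation.  Because both the GPD log-attenuation and b scale as
   G², D⊥ depends only on (R, δ, Δ, D0), not on gradient strength, which is
   what justifies fitting a single D⊥ across shells that share the timing.
3. :func:`smt_powder_signal` — the spherical mean (powder average) of an
   axially symmetric compartment with diffusivities (D∥, D⊥), the quantity
   the multi-shell fit operates on.

:func:`add_rician_noise` corrupts signals the way magnitude MR images are
corrupted: magnitude of a complex Gaussian perturbation with per-channel
standard deviation 1/SNR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf, jnp_zeros

from .protocol import GYROMAGNETIC_RATIO_PROTON, ProtocolError

__all__ = [
    "CylinderCompartment",
    "gpd_perpendicular_signal",
    "effective_Dperp",
    "smt_powder_signal",
    "add_rician_noise",
]

#: µm²/ms → m²/s
_D_SI = 1e-9
#: µm → m
_R_SI = 1e-6
#: number of J1' roots retained in the GPD series by default; at the
#: protocol's (δ, Δ) adding further terms changes the signal by < 1e-8.
DEFAULT_N_ROOTS = 20

_root_cache: dict = {}


def _j1prime_roots(n):
    if n not in _root_cache:
        _root_cache[n] = jnp_zeros(1, n)
    return _root_cache[n]


@dataclass(frozen=True)
class CylinderCompartment:
    """Biophysical parameters of the intra-axonal compartment.

    R in µm, D0 (intrinsic axial diffusivity) and Dperp in µm²/ms, va the
    intra-axonal signal fraction.
    """

    R: float
    D0: float
    Dperp: float = 0.0
    va: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.va <= 1.0):
            raise ValueError("va must lie in [0, 1]")
        if not (0.0 <= self.Dperp <= self.D0):
            raise ValueError("require 0 <= Dperp <= D0")
        if self.R < 0:
            raise ValueError("R must be non-negative")


def gpd_perpendicular_signal(radius_um, G, delta, Delta, D0,
                             gamma=GYROMAGNETIC_RATIO_PROTON,
                             n_roots=DEFAULT_N_ROOTS):
    """GPD attenuation perpendicular to a cylinder of radius R.

    Parameters
    ----------
    radius_um : array_like
        Cylinder radius R, µm.  R = 0 returns 1 (no restriction → no
        dephasing from the perpendicular component).
    G, delta, Delta : float
        PGSE shell: gradient strength (T/m), pulse duration and separation (s).
    D0 : float
        Intrinsic diffusivity inside the cylinder, µm²/ms.
    gamma : float
        Gyromagnetic ratio, rad s^-1 T^-1.
    n_roots : int
        Number of Bessel-derivative roots retained in the series.

    Returns
    -------
    ndarray or float
        S⊥/S0 ∈ (0, 1].

    Notes
    -----
    With a_m the m-th positive root of J1' and κ_m = D a_m²/R², the
    log-attenuation is

        −ln S⊥ = γ²G² Σ_m B_m [2κ_m δ − 2 + 2e^{−κ_m δ} + 2e^{−κ_m Δ}
                                − e^{−κ_m (Δ−δ)} − e^{−κ_m (Δ+δ)}] / κ_m²,

    where B_m = 2R²/(a_m²(a_m²−1)) are the coefficients of the eigenfunction
    expansion of the transverse displacement autocorrelation (Σ B_m = R²/4).
    """
    if D0 <= 0:
        raise ValueError("D0 must be positive")
    if delta <= 0 or Delta < delta:
        raise ProtocolError("require delta > 0 and Delta >= delta")
    if G < 0:
        raise ProtocolError("negative gradient strength")
    R = np.atleast_1d(np.asarray(radius_um, dtype=float))
    if np.any(R < 0):
        raise ValueError("radius must be non-negative")
    out = np.ones_like(R)
    if G > 0:
        pos = R > 0
        if pos.any():
            Rm = R[pos, None] * _R_SI                       # (n, 1)
            D = D0 * _D_SI
            a = _j1prime_roots(n_roots)[None, :]            # (1, m)
            kappa = D * a**2 / Rm**2
            bracket = (
                2.0 * kappa * delta - 2.0
                + 2.0 * np.exp(-kappa * delta)
                + 2.0 * np.exp(-kappa * Delta)
                - np.exp(-kappa * (Delta - delta))
                - np.exp(-kappa * (Delta + delta))
            )
            B = 2.0 * Rm**2 / (a**2 * (a**2 - 1.0))
            ln_s = -((gamma * G) ** 2) * np.sum(B * bracket / kappa**2, axis=1)
            out[pos] = np.exp(ln_s)
    return out if np.ndim(radius_um) else float(out[0])


def effective_Dperp(radius_um, delta, Delta, D0,
                    gamma=GYROMAGNETIC_RATIO_PROTON, G=0.5,
                    n_roots=DEFAULT_N_ROOTS):
    """Apparent perpendicular diffusivity D⊥ = −ln(S⊥)/b, µm²/ms.

    The GPD log-attenuation and b are both proportional to G², so the G in
    the ratio cancels exactly: any positive reference gradient gives the
    same D⊥, and shells sharing (δ, Δ) share one D⊥.  Strictly increasing
    in R; R = 0 gives 0.
    """
    from .protocol import compute_bvalue

    s = gpd_perpendicular_signal(radius_um, G, delta, Delta, D0,
                                 gamma=gamma, n_roots=n_roots)
    b = compute_bvalue(G, delta, Delta, gamma)              # s/mm²
    # −lnS / b is in mm²/s; 1 mm²/s = 1e3 µm²/ms
    return -np.log(s) / b * 1e3


def smt_powder_signal(b, va, Dpar, Dperp):
    """Spherical mean of an axially symmetric Gaussian compartment.

    Parameters
    ----------
    b : array_like
        Diffusion weighting, s/mm².
    va : float
        Intra-axonal signal fraction ∈ [0, 1].
    Dpar, Dperp : float or array_like
        Parallel and perpendicular diffusivities, µm²/ms, with Dperp <= Dpar.

    Returns
    -------
    ndarray or float
        S̄/S0 = va · e^{−b D⊥} · √(π/(4x)) · erf(√x),  x = b(D∥ − D⊥),
        which is the exact average of e^{−b(D⊥ + (D∥−D⊥)cos²θ)} over the
        sphere.  A 3-term Taylor branch handles x → 0 (isotropic limit).
    """
    b = np.asarray(b, dtype=float)
    Dpar = np.asarray(Dpar, dtype=float)
    Dperp = np.asarray(Dperp, dtype=float)
    if np.any(b < 0):
        raise ValueError("b must be non-negative")
    if np.any(Dperp < 0) or np.any(Dperp > Dpar * (1 + 1e-12) + 1e-300):
        raise ValueError("require 0 <= Dperp <= Dpar")
    # b[s/mm²] · D[µm²/ms] → dimensionless requires the factor 1e-3
    x = b * (Dpar - Dperp) * 1e-3
    x = np.maximum(x, 0.0)
    small = x < 1e-6
    xs = np.where(small, 0.0, x)
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(
            small,
            1.0 - x / 3.0 + x**2 / 10.0,
            np.sqrt(np.pi / (4.0 * np.where(small, 1.0, xs))) * erf(np.sqrt(xs)),
        )
    out = va * np.exp(-b * Dperp * 1e-3) * factor
    return out if out.ndim else float(out)


def add_rician_noise(signal, snr, rng):
    """Corrupt ``signal`` with Rician noise at the given SNR.

    The noise model is the magnitude of the complex signal after adding
    independent Gaussian noise of standard deviation 1/SNR to the real and
    imaginary channels (signal assumed real, normalized to S0 = 1).
    ``snr = np.inf`` returns the input unchanged.
    """
    if snr <= 0:
        raise ValueError("SNR must be positive")
    signal = np.asarray(signal, dtype=float)
    if np.isinf(snr):
        return signal.copy() if signal.ndim else float(signal)
    sigma = 1.0 / snr
    n_re = rng.normal(0.0, sigma, size=signal.shape)
    n_im = rng.normal(0.0, sigma, size=signal.shape)
    out = np.hypot(signal + n_re, n_im)
    return out if out.ndim else float(out)
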