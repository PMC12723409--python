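"""Independent numerical oracles used to validate the closed-form signal model.

These deliberately avoid the package's analytic expressions: the restricted
perpendicular signal is obtained by adaptive quadrature of the phase-variance
double integral (reduced to 1D convolution-weight integrals per eigenmode),
and the spherical mean by brute-force averaging over a dense deterministic
direction set.
"""

import numpy as np
from scipy.integrate import quad
from scipy.special import jnp_zeros

GAMMA = 2.6752218744e8


def gpd_quadrature_signal(radius_um, G, delta, Delta, D0_um2_ms,
                          gamma=GAMMA, n_roots=20):
    """Perpendicular PGSE attenuation via numeric phase-variance quadrature.

    The transverse displacement autocorrelation inside a cylinder is
    K(τ) = Σ_m B_m e^{−κ_m τ} with κ_m = D a_m²/R² and
    B_m = 2R²/(a_m²(a_m²−1)) (so that K(0) = R²/4, the variance of one
    Cartesian coordinate on a disk).  The phase variance of the two
    rectangular pulses is a double time integral of g(t)g(t')K(|t−t'|),
    which collapses to 1D integrals with triangular weights; these are
    evaluated with adaptive quadrature rather than in closed form.
    """
    R = radius_um * 1e-6
    D = D0_um2_ms * 1e-9
    roots = jnp_zeros(1, n_roots)
    phi2 = 0.0
    for a in roots:
        kappa = D * a**2 / R**2
        B = 2.0 * R**2 / (a**2 * (a**2 - 1.0))
        i_same, _ = quad(lambda tau: 2.0 * (delta - tau) * np.exp(-kappa * tau),
                         0.0, delta, limit=200)
        i_cross, _ = quad(
            lambda tau: (delta - abs(tau - Delta)) * np.exp(-kappa * tau),
            Delta - delta, Delta + delta, points=[Delta], limit=200)
        phi2 += B * (2.0 * i_same - 2.0 * i_cross)
    phi2 *= (gamma * G) ** 2
    return float(np.exp(-phi2 / 2.0))


def dense_directions(n=20001):
    """Deterministic near-uniform direction set (golden-angle spiral)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + 5.0**0.5) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def spherical_mean_quadrature(b, va, Dpar, Dperp, n_dirs=20001):
    """Arithmetic mean of the compartment signal over a dense direction set."""
    cos2 = dense_directions(n_dirs)[:, 2] ** 2
    return float(va * np.mean(np.exp(-b * (Dperp + (Dpar - Dperp) * cos2) * 1e-3)))
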