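"""Synthetic inputs with the statistical structure the analysis assumes.

Every generator returns a ``(data, truth)`` pair so downstream results can
be checked against known ground truth.  The defaults encode the study
conditions the pipeline targets:

* axon diameter distributions are right-skewed; the conventional-embedding
  ("epon-like") default is calibrated to mode 0.31 µm / p90 0.66 µm, the
  cryo-fixed ("cryo-like") default to mode 0.39 µm / p90 1.42 µm (the
  heavier tail reflecting diameter-dependent shrinkage in embedded tissue);
* per-axon g-ratios scatter around a mean of 0.64;
* diffusion signals follow the three-shell high-b protocol with Rician
  noise at SNR 50;
* evoked LFP traces carry a positive deflection at 5.6 ms (P1) and a
  negative one at 11.8 ms (N1) plus trial noise.

Law parameters (gamma by default, lognormal available) are solved
numerically from the (mode, p90) targets at generator-build time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import gamma as gamma_dist
from skimage.draw import ellipse as draw_ellipse

from .cylinder import add_rician_noise, effective_Dperp
from .lfp import LFPTrace
from .protocol import AXON, MYELIN, DWIDataset, LabelMask, \
    PGSEProtocol, uniform_directions

__all__ = [
    "GeneratorSpec",
    "PackingError",
    "solve_diameter_law",
    "gen_diameter_sample",
    "gen_tem_mask",
    "gen_dmri_signals",
    "gen_lfp",
]

_Z90 = 1.2815515655446004  # standard normal 90th-percentile quantile


class PackingError(RuntimeError):
    """Could not place the requested number of axons without overlap."""


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of all synthetic generators (one seed governs them all)."""

    seed: int = 0
    # diameter law
    diameter_law: str = "gamma"         # "gamma" | "lognormal"
    target_mode_um: float = 0.31
    target_p90_um: float = 0.66
    # EM mask geometry
    n_axons: int = 50
    g_mean: float = 0.64
    g_sd: float = 0.05
    mask_size_px: int = 2560
    pixel_size_um: float = 0.005
    preparation: str = "epon"
    min_render_diameter_um: float = 0.12
    # dMRI
    snr: float = 50.0
    va: float = 0.7
    d0: float = 0.45                    # µm²/ms (ex vivo fixed tissue)
    # LFP template
    lfp_fs_hz: float = 30000.0
    lfp_n_trials: int = 50
    lfp_p1_ms: float = 5.6
    lfp_n1_ms: float = 11.8
    lfp_p1_amp_uv: float = 15.0
    lfp_n1_amp_uv: float = -40.0
    lfp_p1_width_ms: float = 0.8
    lfp_n1_width_ms: float = 2.5
    lfp_noise_sd_uv: float = 5.0
    lfp_noise_corr_ms: float = 0.5      # noise autocorrelation scale (LFP band)

    @classmethod
    def epon_like(cls, **overrides):
        return cls(**overrides)

    @classmethod
    def cryo_like(cls, **overrides):
        overrides.setdefault("target_mode_um", 0.39)
        overrides.setdefault("target_p90_um", 1.42)
        overrides.setdefault("preparation", "cryo")
        return cls(**overrides)


def solve_diameter_law(law, mode, p90):
    """Solve law parameters from (mode, p90) targets.

    gamma: mode = (k−1)θ (needs k > 1), p90 = F⁻¹(0.9; k)·θ.
    lognormal: mode = e^{µ−σ²}, p90 = e^{µ+z₀.₉σ}.

    Returns a dict with the law name, its parameters, and the analytic mode
    and p90.  Raises ``ValueError`` for infeasible target pairs.
    """
    if not (0 < mode < p90):
        raise ValueError("targets must satisfy 0 < mode < p90")
    ratio = p90 / mode
    if law == "gamma":
        def f(k):
            return gamma_dist.ppf(0.9, k) / (k - 1.0) - ratio

        lo, hi = 1.0 + 1e-6, 2e3
        if f(hi) > 0:
            raise ValueError(f"p90/mode ratio {ratio:.3f} too close to 1 for a gamma law")
        k = brentq(f, lo, hi, xtol=1e-12)
        theta = mode / (k - 1.0)
        return {
            "law": "gamma", "shape": k, "scale": theta,
            "mode": (k - 1.0) * theta,
            "p90": gamma_dist.ppf(0.9, k, scale=theta),
        }
    if law == "lognormal":
        lnr = np.log(ratio)
        sigma = (-_Z90 + np.sqrt(_Z90**2 + 4.0 * lnr)) / 2.0
        mu = np.log(mode) + sigma**2
        return {
            "law": "lognormal", "mu": mu, "sigma": sigma,
            "mode": float(np.exp(mu - sigma**2)),
            "p90": float(np.exp(mu + _Z90 * sigma)),
        }
    raise ValueError(f"unknown diameter law {law!r}")


def gen_diameter_sample(spec: GeneratorSpec, n, rng=None):
    """i.i.d. axon diameters (µm) plus the law's analytic truth."""
    params = solve_diameter_law(spec.diameter_law, spec.target_mode_um,
                                spec.target_p90_um)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if params["law"] == "gamma":
        d = rng.gamma(params["shape"], params["scale"], size=n)
    else:
        d = rng.lognormal(params["mu"], params["sigma"], size=n)
    return d, params


# ---------------------------------------------------------------------------
# EM label masks
# ---------------------------------------------------------------------------

def _place_axons(spec, diameters, aspects, gs, flags, rng, margin_extra=6):
    """Non-overlapping centers by rejection sampling on bounding circles.

    Fibers flagged ``border`` are pinned to row 2 (inside the 4-px exclusion
    frame) and participate in the same overlap checks as everything else.
    """
    size = spec.mask_size_px
    placed = []  # (r, c, r_bound)
    centers = []
    for d, aspect, g, flag in zip(diameters, aspects, gs, flags):
        semi_minor_in = d / (2.0 * spec.pixel_size_um)
        semi_major_in = semi_minor_in / aspect
        semi_major_out = semi_major_in / g
        # pad by the myelin thickness so nearest-axon myelin assignment can
        # never prefer a neighboring fiber's axon over the fiber's own
        r_bound = semi_major_out + (semi_major_out - semi_major_in) + 3.0
        margin = r_bound + margin_extra
        if 2 * margin >= size:
            raise PackingError("axon too large for the mask; increase mask_size_px")
        for _ in range(400):
            r = 2.0 if flag == "border" else rng.uniform(margin, size - margin)
            c = rng.uniform(margin, size - margin)
            if all((r - pr) ** 2 + (c - pc) ** 2 > (r_bound + pb) ** 2
                   for pr, pc, pb in placed):
                placed.append((r, c, r_bound))
                centers.append((r, c))
                break
        else:
            raise PackingError(
                f"could not place {len(diameters)} axons in a "
                f"{size}px mask; reduce n_axons or enlarge the mask"
            )
    return centers


def _render_fiber(classes, r, c, semi_minor_in, semi_major_in, g, angle,
                  myelinated=True, coverage_gap_frac=0.0):
    """Draw one fiber: myelin annulus (optional, possibly with a gap) + axon."""
    if myelinated:
        rr, cc = draw_ellipse(r, c, semi_minor_in / g, semi_major_in / g,
                              shape=classes.shape, rotation=angle)
        if coverage_gap_frac > 0:
            ang = np.arctan2(rr - r, cc - c)
            keep = ~((ang > 0) & (ang < 2 * np.pi * coverage_gap_frac))
            rr, cc = rr[keep], cc[keep]
        classes[rr, cc] = MYELIN
    rr, cc = draw_ellipse(r, c, semi_minor_in, semi_major_in,
                          shape=classes.shape, rotation=angle)
    classes[rr, cc] = AXON


def gen_tem_mask(spec: GeneratorSpec, inject=None, rng=None):
    """Render a label mask of non-overlapping myelinated axons + truth table.

    Inner ellipses have their minor axis equal to the drawn diameter (the
    quantity the morphometry reports); the myelin annulus scales both axes
    by 1/g with per-axon g ~ Normal(g_mean, g_sd) clipped to (0.4, 0.9).
    ``inject`` optionally adds rule violations, e.g.
    ``{"border": 1, "unmyelinated": 1, "high_eccentricity": 1,
    "low_coverage": 1}``; each appears in the truth table with its flag.

    Diameters below ``min_render_diameter_um`` are resampled: the mask
    emulates the population the pixel grid can represent, not the full law.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    inject = dict(inject or {})
    n_clean = spec.n_axons

    diams = []
    while len(diams) < n_clean:
        d, _ = gen_diameter_sample(spec, n_clean, rng=rng)
        diams.extend(d[d >= spec.min_render_diameter_um].tolist())
    diams = np.array(diams[:n_clean])
    aspects = rng.uniform(0.8, 1.0, size=n_clean)
    gs = np.clip(rng.normal(spec.g_mean, spec.g_sd, size=n_clean), 0.4, 0.9)
    angles = rng.uniform(0, np.pi, size=n_clean)
    flags = ["clean"] * n_clean

    # injected violations reuse mid-range diameters so they are unambiguous
    for kind, count in inject.items():
        for _ in range(int(count)):
            diams = np.append(diams, rng.uniform(0.3, 0.5))
            aspects = np.append(aspects, 0.15 if kind == "high_eccentricity"
                                else rng.uniform(0.85, 1.0))
            gs = np.append(gs, spec.g_mean)
            angles = np.append(angles, rng.uniform(0, np.pi))
            flags.append(kind)

    # place big fibers first: sequential rejection packing jams far later
    # when the large bounding circles go in before the small ones
    sizes = diams / (aspects * gs)
    order = np.argsort(-sizes, kind="stable")
    centers_sorted = _place_axons(
        spec, diams[order], aspects[order], gs[order],
        [flags[i] for i in order], rng)
    centers = [None] * len(order)
    for pos, idx in enumerate(order):
        centers[idx] = centers_sorted[pos]
    classes = np.zeros((spec.mask_size_px,) * 2, dtype=np.int16)
    rows = []
    for (r, c), d, aspect, g, angle, flag in zip(
            centers, diams, aspects, gs, angles, flags):
        semi_minor_in = d / (2.0 * spec.pixel_size_um)
        semi_major_in = semi_minor_in / aspect
        _render_fiber(
            classes, r, c, semi_minor_in, semi_major_in, g, angle,
            myelinated=(flag != "unmyelinated"),
            coverage_gap_frac=0.3 if flag == "low_coverage" else 0.0,
        )
        rows.append({
            "d_inner_um": d,
            "d_outer_um": d / g,
            "g": g,
            "eccentricity": float(np.sqrt(1.0 - aspect**2)),
            "violation": flag,
            "center_r": r, "center_c": c,
        })
    mask = LabelMask(classes=classes, pixel_size=spec.pixel_size_um,
                     preparation=spec.preparation)
    return mask, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Diffusion-weighted datasets
# ---------------------------------------------------------------------------

def gen_dmri_signals(spec: GeneratorSpec, protocol: PGSEProtocol,
                     shape=(4, 4, 4), diameter=None, axis=(0.0, 0.0, 1.0),
                     rng=None):
    """Direction-resolved synthetic DWI dataset + per-voxel truth.

    Per voxel, an intra-axonal cylinder signal with the given (or law-drawn)
    diameter: the GPD-derived effective D⊥ turns the cylinder into an
    axially symmetric compartment, evaluated along the protocol's direction
    set, scaled by ``va``, with Rician noise at ``spec.snr``
    (``snr = inf`` → noiseless).  b=0 images are included.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n_vox = int(np.prod(shape))
    if diameter is None:
        d_vox, _ = gen_diameter_sample(spec, n_vox, rng=rng)
    else:
        d_vox = np.full(n_vox, float(diameter))

    dirs = uniform_directions(protocol.n_directions)
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    cos2 = (dirs @ axis) ** 2
    b_shells = protocol.bvalues

    bvals = np.concatenate([
        np.zeros(protocol.n_b0),
        np.repeat(b_shells, protocol.n_directions),
    ])
    bvecs = np.vstack([
        np.zeros((protocol.n_b0, 3)),
        np.tile(dirs, (len(b_shells), 1)),
    ])

    volume = np.empty(shape + (len(bvals),))
    truth_d = np.empty(n_vox)
    truth_dperp = np.empty(n_vox)
    for i, d in enumerate(d_vox):
        dp = float(effective_Dperp(d / 2.0, protocol.delta, protocol.Delta,
                                   spec.d0, gamma=protocol.gamma))
        sig_dirs = spec.va * np.exp(
            -np.outer(b_shells, dp + (spec.d0 - dp) * cos2) * 1e-3
        ).ravel()
        clean = np.concatenate([np.ones(protocol.n_b0), sig_dirs])
        noisy = add_rician_noise(clean, spec.snr, rng)
        volume[np.unravel_index(i, shape)] = noisy
        truth_d[i] = d
        truth_dperp[i] = dp

    dataset = DWIDataset(volume=volume, bvals=bvals, bvecs=bvecs,
                         voxel_size=0.125)
    truth = pd.DataFrame({
        "diameter_um": truth_d,
        "Dperp_um2_ms": truth_dperp,
        "va": spec.va,
        "d0": spec.d0,
    })
    return dataset, truth


# ---------------------------------------------------------------------------
# Evoked LFP traces
# ---------------------------------------------------------------------------

def gen_lfp(spec: GeneratorSpec, rng=None, pre_ms=60.0, post_ms=40.0):
    """Multi-trial stereotrode LFP with P1/N1 deflections + truth latencies.

    Each trial is a constant offset (drift surrogate) plus Gaussian-shaped
    deflections at the P1 and N1 latencies with small trial-to-trial gain
    jitter, band-limited noise per channel (white noise smoothed over
    ``lfp_noise_corr_ms``, since LFP power lives well below the Nyquist of
    the recording), and a slight gain mismatch between the two channels.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    fs = spec.lfp_fs_hz
    n_pre = int(round(pre_ms * fs / 1000.0))
    n_post = int(round(post_ms * fs / 1000.0))
    n_samples = n_pre + n_post
    t_ms = (np.arange(n_samples) - n_pre) * 1000.0 / fs

    def bump(lat, amp, width):
        return amp * np.exp(-0.5 * ((t_ms - lat) / width) ** 2)

    template = (bump(spec.lfp_p1_ms, spec.lfp_p1_amp_uv, spec.lfp_p1_width_ms)
                + bump(spec.lfp_n1_ms, spec.lfp_n1_amp_uv, spec.lfp_n1_width_ms))

    # Gaussian smoothing kernel that band-limits the trial noise
    n_k = max(1, int(round(spec.lfp_noise_corr_ms * fs / 1000.0)))
    k = np.exp(-0.5 * (np.arange(-3 * n_k, 3 * n_k + 1) / n_k) ** 2)
    k /= np.sqrt(np.sum(k**2))          # preserves the noise SD

    channel_gain = np.array([1.0, 0.97])
    data = np.empty((spec.lfp_n_trials, 2, n_samples))
    for trial in range(spec.lfp_n_trials):
        gain = rng.normal(1.0, 0.05)
        offset = rng.normal(0.0, 2.0)
        base = gain * template + offset
        for ch in range(2):
            white = rng.normal(0.0, spec.lfp_noise_sd_uv,
                               size=n_samples + len(k) - 1)
            noise = np.convolve(white, k, mode="valid")
            data[trial, ch] = channel_gain[ch] * base + noise

    trace = LFPTrace(data=data, fs=fs, stim_index=n_pre)
    truth = {"p1_ms": spec.lfp_p1_ms, "n1_ms": spec.lfp_n1_ms}
    return trace, truth
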