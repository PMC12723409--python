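"""Joint structure–function report across modalities.

The report mirrors the comparison logic of the study's summary figure: axon
diameter distributions from conventional-embedding EM (raw, shrinkage
corrected, MR-weighted, corrected+weighted), cryo-fixed EM (raw, weighted),
and dMRI voxel estimates are placed on a common diameter axis, and every
diameter summary is paired with the conduction time it predicts through
TCT = L·g/(5.5·d).  Conversely the measured conduction time is mapped to
the diameter it implies.

:func:`run_report` drives a fully synthetic single-seed study (all
generators) or any subset of supplied real inputs; missing modalities are
reported as absent, not failed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .lfp import average_and_baseline, detect_peaks, reliability_cov
from .morphometry import distribution_stats
from .protocol import PGSEProtocol
from .smtfit import fit_smt_volume, roi_diameter_distribution
from .structure_function import (apply_shrinkage_correction,
                                 mr_weighted_diameter, predict_diameter,
                                 predict_tct, shrinkage_factor)
from .synth import GeneratorSpec, gen_diameter_sample, gen_dmri_signals, gen_lfp

__all__ = ["StudyConfig", "StudyReport", "run_report", "human_extrapolation"]


@dataclass(frozen=True)
class StudyConfig:
    """Constants and synthetic-input sizes for one study run."""

    seed: int = 0
    L_mm: float = 11.47          # tract length (group mean)
    g: float = 0.64              # g-ratio (EM group mean)
    d0: float = 0.45             # intrinsic diffusivity, µm²/ms (ex vivo)
    snr: float = 50.0
    n_em_sample: int = 20000     # diameters per EM-like modality
    dmri_shape: tuple = (4, 4, 4)


@dataclass
class StudyReport:
    """Per-modality summaries with paired TCT predictions."""

    L_mm: float
    g: float
    modalities: dict = field(default_factory=dict)
    shrinkage: dict | None = None
    tct_measured_ms: float | None = None
    predicted_diameter_um: float | None = None
    provenance: dict = field(default_factory=dict)

    def add_modality(self, name, values=None, stats=None, d_w=None, counts=None):
        """Summarize one modality and pair each summary with a predicted TCT."""
        if stats is None and values is not None:
            stats = distribution_stats(np.asarray(values))
        entry = {}
        if stats is not None:
            entry.update(stats.as_dict())
            entry["predicted_tct_mean_ms"] = predict_tct(stats.mean, self.L_mm, self.g)
            entry["predicted_tct_mode_ms"] = predict_tct(stats.mode, self.L_mm, self.g)
        if d_w is not None:
            entry["d_w"] = d_w
            entry["predicted_tct_d_w_ms"] = predict_tct(d_w, self.L_mm, self.g)
        if counts:
            entry["counts"] = counts
        self.modalities[name] = entry
        return entry

    def to_json(self, indent=2):
        """Deterministic JSON (sorted keys, no timestamps)."""
        def default(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o).__name__)

        return json.dumps(dataclasses.asdict(self), indent=indent,
                          sort_keys=True, default=default)


def run_report(config: StudyConfig, epon_diameters=None, cryo_diameters=None,
               dmri_dataset=None, dmri_roi=None, lfp_trace=None,
               protocol=None, synthesize_missing=True):
    """Compute the joint structure–function report.

    Any modality input left as ``None`` is synthesized from ``config.seed``
    (when ``synthesize_missing``) or reported as absent.  With no modality
    available at all a ``ValueError`` is raised.
    """
    if protocol is None:
        protocol = PGSEProtocol.diameter_protocol()
    report = StudyReport(L_mm=config.L_mm, g=config.g)
    rng = np.random.default_rng(config.seed)

    if epon_diameters is None and synthesize_missing:
        spec = GeneratorSpec.epon_like(seed=config.seed)
        epon_diameters, _ = gen_diameter_sample(spec, config.n_em_sample, rng=rng)
    if cryo_diameters is None and synthesize_missing:
        spec = GeneratorSpec.cryo_like(seed=config.seed)
        cryo_diameters, _ = gen_diameter_sample(spec, config.n_em_sample, rng=rng)
    if dmri_dataset is None and synthesize_missing:
        # one coherent fiber population per voxel, at the tail-weighted
        # diameter of the (cryo-like) tissue law — the quantity a dMRI voxel
        # effectively reports
        cryo_spec = GeneratorSpec.cryo_like(seed=config.seed, snr=config.snr,
                                            d0=config.d0)
        tissue, _ = gen_diameter_sample(cryo_spec, config.n_em_sample,
                                        rng=np.random.default_rng(config.seed + 1))
        d_w_tissue = mr_weighted_diameter(tissue)
        dmri_dataset, _ = gen_dmri_signals(cryo_spec, protocol,
                                           shape=config.dmri_shape,
                                           diameter=d_w_tissue, rng=rng)
    if lfp_trace is None and synthesize_missing:
        lfp_trace, _ = gen_lfp(GeneratorSpec(seed=config.seed), rng=rng)

    have_any = False

    epon_stats = cryo_stats = None
    if epon_diameters is not None:
        epon_diameters = np.asarray(epon_diameters, float)
        epon_stats = distribution_stats(epon_diameters)
        report.add_modality("epon", stats=epon_stats,
                            d_w=mr_weighted_diameter(epon_diameters))
        have_any = True
    if cryo_diameters is not None:
        cryo_diameters = np.asarray(cryo_diameters, float)
        cryo_stats = distribution_stats(cryo_diameters)
        report.add_modality("cryo", stats=cryo_stats,
                            d_w=mr_weighted_diameter(cryo_diameters))
        have_any = True

    if epon_stats is not None and cryo_stats is not None:
        s = shrinkage_factor(epon_stats, cryo_stats)
        report.shrinkage = {"s_mode": s.s_mode, "s_p90": s.s_p90,
                            "s_general": s.s_general}
        corrected = apply_shrinkage_correction(epon_diameters, s.s_general)
        report.add_modality("epon_corrected",
                            stats=distribution_stats(corrected),
                            d_w=mr_weighted_diameter(corrected))

    if dmri_dataset is not None:
        from .morphometry import EmptyDistributionError

        dmap = fit_smt_volume(dmri_dataset, protocol, config.d0, roi=dmri_roi)
        try:
            stats, counts = roi_diameter_distribution(dmap)
        except EmptyDistributionError:
            # every ROI voxel collapsed to zero / below the discard threshold
            # (expected when the tissue's effective diameter sits below the
            # acquisition's sensitivity band)
            stats = None
            counts = {
                "n_roi": int(dmap.roi.sum()),
                "n_valid": 0,
                "n_zero": int(((dmap.state == dmap.ZERO) & dmap.roi).sum()),
                "n_discarded": int(((dmap.state == dmap.DISCARDED) & dmap.roi).sum()),
                "n_invalid": int(((dmap.state == dmap.INVALID) & dmap.roi).sum()),
            }
        report.add_modality("dmri", stats=stats, counts=counts)
        have_any = True

    if lfp_trace is not None:
        mean_trace = average_and_baseline(lfp_trace)
        peaks = detect_peaks(mean_trace, lfp_trace.fs, lfp_trace.stim_index)
        if peaks.n1_latency is not None:
            peaks.cov_n1 = reliability_cov(lfp_trace, peaks.n1_latency)
        entry = {
            "p1_latency_ms": peaks.p1_latency,
            "n1_latency_ms": peaks.n1_latency,
            "cov_n1": peaks.cov_n1,
            "reliable": peaks.reliable,
        }
        if peaks.p1_latency is not None:
            report.tct_measured_ms = peaks.p1_latency
            report.predicted_diameter_um = predict_diameter(
                peaks.p1_latency, config.L_mm, config.g)
            entry["predicted_diameter_um"] = report.predicted_diameter_um
        report.modalities["opto_elphys"] = entry
        have_any = True

    if not have_any:
        raise ValueError("no modality inputs available")

    report.provenance = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "version": __version__,
    }
    return report


def human_extrapolation(tct_range_ms, length_range_mm, g=0.7):
    """Diameter range implied by a (TCT, pathway length) envelope.

    The extremes are paired to span the widest diameter interval: the
    minimum diameter pairs the longest conduction time with the shortest
    pathway, the maximum the shortest time with the longest pathway.
    """
    t_lo, t_hi = tct_range_ms
    l_lo, l_hi = length_range_mm
    if t_lo > t_hi or l_lo > l_hi:
        raise ValueError("ranges must be (low, high)")
    return (predict_diameter(t_hi, l_lo, g), predict_diameter(t_lo, l_hi, g))
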