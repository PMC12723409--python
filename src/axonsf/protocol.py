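"""Acquisition protocol constants, standard-format I/O, configuration and logging.

Conventions used throughout the package
---------------------------------------
* Protocol timing and gradient quantities are SI: gradient strength ``G`` in
  T/m, durations in seconds, gyromagnetic ratio in rad s^-1 T^-1.
* Microstructure quantities use the field's customary units: lengths in µm,
  diffusivities in µm²/ms, diffusion weighting ``b`` in s/mm².
* Conversions between the two systems happen exactly once, at function
  boundaries, never implicitly inside numerical kernels.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "GYROMAGNETIC_RATIO_PROTON",
    "B0_THRESHOLD_S_MM2",
    "ProtocolError",
    "FormatError",
    "compute_bvalue",
    "PGSEProtocol",
    "DWIDataset",
    "read_dwi",
    "write_dwi",
    "LabelMask",
    "read_label_mask",
    "write_label_mask",
    "RunConfig",
    "uniform_directions",
    "setup_logging",
]

log = logging.getLogger("axonsf")

#: Proton gyromagnetic ratio, rad s^-1 T^-1.
GYROMAGNETIC_RATIO_PROTON = 2.6752218744e8

#: Measurements with b below this value (s/mm²) are treated as unweighted
#: (b=0) images; the tolerance absorbs header rounding.
B0_THRESHOLD_S_MM2 = 50.0

#: Label codes used for semantic classes everywhere in the package.
BACKGROUND, AXON, MYELIN = 0, 1, 2


class ProtocolError(ValueError):
    """Invalid or inconsistent acquisition protocol."""


class FormatError(ValueError):
    """Malformed input file or table."""


def compute_bvalue(G, delta, Delta, gamma=GYROMAGNETIC_RATIO_PROTON):
    """Diffusion weighting of a rectangular PGSE pulse pair, in s/mm².

    Parameters
    ----------
    G : float
        Gradient strength, T/m.  ``G = 0`` gives ``b = 0``.
    delta : float
        Gradient pulse duration δ, s.
    Delta : float
        Gradient pulse separation Δ, s.  Must satisfy ``Delta >= delta``.
    gamma : float
        Gyromagnetic ratio, rad s^-1 T^-1.

    Returns
    -------
    float
        ``b = γ² G² δ² (Δ − δ/3)`` converted from s/m² to s/mm².
    """
    if delta <= 0 or Delta <= 0 or gamma <= 0:
        raise ProtocolError("timing parameters and gamma must be positive")
    if Delta < delta:
        raise ProtocolError(f"Delta ({Delta}) must be >= delta ({delta})")
    if np.any(np.asarray(G) < 0):
        raise ProtocolError("gradient strength must be non-negative")
    b_si = (gamma * np.asarray(G) * delta) ** 2 * (Delta - delta / 3.0)  # s/m²
    return b_si * 1e-6


@dataclass(frozen=True)
class PGSEProtocol:
    """A multi-shell pulsed-gradient spin-echo acquisition.

    ``shells`` is a sequence of ``(G, b_nominal)`` pairs with G in T/m and the
    nominal b-value in s/mm².  On construction each shell's b-value is
    recomputed from ``(G, delta, Delta, gamma)`` and checked against the
    nominal value to within ``b_rtol`` relative; pass ``b_rtol=None`` to load
    a protocol whose printed b-value is not self-consistent (e.g. a vendor
    rounding), which is logged rather than silently accepted.
    """

    shells: tuple
    delta: float
    Delta: float
    gamma: float = GYROMAGNETIC_RATIO_PROTON
    n_directions: int = 30
    n_b0: int = 9
    b_rtol: float | None = 1e-3

    def __post_init__(self):
        object.__setattr__(self, "shells", tuple((float(G), float(b)) for G, b in self.shells))
        if self.delta <= 0 or self.Delta < self.delta:
            raise ProtocolError("require delta > 0 and Delta >= delta")
        for G, b_nom in self.shells:
            if G < 0:
                raise ProtocolError("negative gradient strength")
            b = compute_bvalue(G, self.delta, self.Delta, self.gamma)
            if self.b_rtol is not None:
                if b_nom <= 0 or abs(b - b_nom) / b_nom > self.b_rtol:
                    raise ProtocolError(
                        f"shell G={G} T/m: computed b={b:.0f} s/mm² does not match "
                        f"nominal {b_nom:.0f} within {self.b_rtol:.1%}"
                    )
            else:
                log.warning(
                    "PGSEProtocol loaded with b-consistency check relaxed: "
                    "G=%.3f T/m computed b=%.0f vs nominal %.0f s/mm²",
                    G, compute_bvalue(G, self.delta, self.Delta, self.gamma), b_nom,
                )

    @property
    def gradient_strengths(self):
        return np.array([G for G, _ in self.shells])

    @property
    def bvalues(self):
        """Computed (not nominal) b-values per shell, s/mm²."""
        return compute_bvalue(self.gradient_strengths, self.delta, self.Delta, self.gamma)

    @property
    def bvalues_nominal(self):
        return np.array([b for _, b in self.shells])

    @classmethod
    def diameter_protocol(cls):
        """The three-shell high-b protocol used for axon diameter mapping.

        G = [590, 550, 500] mT/m, δ = 8 ms, Δ = 18 ms, 30 directions per
        shell plus nine b=0 images; nominal b = [24450, 21247, 17560] s/mm².
        """
        return cls(
            shells=((0.590, 24450.0), (0.550, 21247.0), (0.500, 17560.0)),
            delta=8e-3,
            Delta=18e-3,
            n_directions=30,
            n_b0=9,
        )

    @classmethod
    def tractography_protocol(cls):
        """Single-shell protocol used for tractography and the tensor fit.

        b = 4000 s/mm² nominal at G = 224 mT/m, δ = 7.5 ms, Δ = 23 ms,
        61 directions.  The printed b-value is not self-consistent with the
        printed (G, δ, Δ) at 0.1%, so the consistency check is relaxed here
        (computed b ≈ 4140 s/mm²); downstream code uses the nominal value.
        """
        return cls(
            shells=((0.224, 4000.0),),
            delta=7.5e-3,
            Delta=23e-3,
            n_directions=61,
            n_b0=1,
            b_rtol=None,
        )


# ---------------------------------------------------------------------------
# Diffusion-weighted volumes (NIfTI + FSL bval/bvec)
# ---------------------------------------------------------------------------

@dataclass
class DWIDataset:
    """A 4D diffusion-weighted volume with its gradient table.

    ``volume`` is (x, y, z, n_meas); ``bvals`` (s/mm²) and ``bvecs`` (n_meas, 3)
    describe each measurement.  Non-zero bvecs must be unit norm within 1e-3.
    """

    volume: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    voxel_size: float = 0.125  # mm

    def __post_init__(self):
        self.volume = np.asarray(self.volume, dtype=float)
        self.bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.volume.ndim != 4:
            raise FormatError("volume must be 4D (x, y, z, measurement)")
        n = self.volume.shape[3]
        if self.bvecs.ndim != 2 or self.bvecs.shape[1] != 3:
            raise FormatError("bvecs must have shape (n_measurements, 3)")
        if len(self.bvals) != n or len(self.bvecs) != n:
            raise FormatError(
                f"gradient table length ({len(self.bvals)}/{len(self.bvecs)}) "
                f"does not match measurement axis ({n})"
            )
        nz = self.bvals >= B0_THRESHOLD_S_MM2
        norms = np.linalg.norm(self.bvecs[nz], axis=1)
        if nz.any() and np.any(np.abs(norms - 1.0) > 1e-3):
            raise FormatError("non-zero bvecs must be unit norm within 1e-3")

    @property
    def b0_mask(self):
        return self.bvals < B0_THRESHOLD_S_MM2

    @property
    def n_b0(self):
        return int(self.b0_mask.sum())

    def shell_bvalues(self):
        """Unique diffusion-weighted b-values (s/mm²), ascending.

        b-values are clustered by rounding to the nearest s/mm², which is the
        resolution of FSL-dialect tables.
        """
        dw = np.round(self.bvals[~self.b0_mask])
        return np.unique(dw)

    def shell_indices(self, b):
        """Measurement indices belonging to the shell with b-value ``b``."""
        return np.nonzero(np.round(self.bvals) == np.round(b))[0]


def read_dwi(nifti_path, bval_path, bvec_path):
    """Read a NIfTI volume plus FSL-dialect bval/bvec tables.

    The bval file is whitespace-separated, one row; the bvec file has three
    rows (x, y, z), one column per measurement.
    """
    img = nib.load(str(nifti_path))
    volume = np.asarray(img.dataobj, dtype=float)
    if volume.ndim == 3:
        volume = volume[..., None]
    bvals = np.loadtxt(bval_path, ndmin=1).ravel()
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] != 3:
        raise FormatError(f"bvec file must have 3 rows, got {bvecs.shape[0]}")
    voxel_size = float(img.header.get_zooms()[0])
    return DWIDataset(volume=volume, bvals=bvals, bvecs=bvecs.T, voxel_size=voxel_size)


def write_dwi(dataset, nifti_path, bval_path, bvec_path):
    """Write a :class:`DWIDataset` as NIfTI + FSL bval/bvec (round-trip safe)."""
    affine = np.diag([dataset.voxel_size] * 3 + [1.0])
    nib.save(nib.Nifti1Image(dataset.volume.astype(np.float64), affine), str(nifti_path))
    np.savetxt(bval_path, dataset.bvals[None, :], fmt="%.6f")
    np.savetxt(bvec_path, dataset.bvecs.T, fmt="%.9f")


# ---------------------------------------------------------------------------
# Labeled axon/myelin masks (TIFF/PNG)
# ---------------------------------------------------------------------------

@dataclass
class LabelMask:
    """A 2D integer label image with semantic classes background/axon/myelin.

    ``classes`` holds the codes 0 (background), 1 (axon), 2 (myelin).
    ``pixel_size`` is the edge length of one pixel in µm; for images that were
    downsampled upstream it must already reflect the downsampling.
    """

    classes: np.ndarray
    pixel_size: float
    preparation: str = "epon"

    def __post_init__(self):
        self.classes = np.asarray(self.classes)
        if self.classes.ndim != 2:
            raise FormatError("label mask must be 2D")
        if not np.issubdtype(self.classes.dtype, np.integer):
            raise FormatError("label mask must be integer-valued")
        if self.pixel_size <= 0:
            raise FormatError("pixel_size must be positive (µm/px)")
        extra = set(np.unique(self.classes)) - {BACKGROUND, AXON, MYELIN}
        if extra:
            raise FormatError(f"unexpected class codes {sorted(extra)}")


def read_label_mask(image_path, pixel_size, class_map=None, preparation="epon",
                    strict=True):
    """Read a TIFF/PNG integer label image into a :class:`LabelMask`.

    ``class_map`` maps raw pixel values to the semantic codes 0/1/2; by
    default raw values are taken as already semantic.  Unknown raw values
    raise :class:`FormatError` in strict mode, or are mapped to background
    (and logged) otherwise.
    """
    path = Path(image_path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        raw = tifffile.imread(str(path))
    else:
        from PIL import Image

        raw = np.asarray(Image.open(path))
    if not np.issubdtype(raw.dtype, np.integer):
        raise FormatError(f"{path.name}: label image must be integer-valued, got {raw.dtype}")
    if class_map is None:
        class_map = {BACKGROUND: BACKGROUND, AXON: AXON, MYELIN: MYELIN}
    out = np.full(raw.shape, -1, dtype=np.int16)
    for raw_value, semantic in class_map.items():
        out[raw == raw_value] = semantic
    unknown = out < 0
    if unknown.any():
        values = sorted(np.unique(raw[unknown]).tolist())
        if strict:
            raise FormatError(f"{path.name}: unknown label values {values}")
        log.warning("%s: mapping unknown label values %s to background", path.name, values)
        out[unknown] = BACKGROUND
    return LabelMask(classes=out, pixel_size=pixel_size, preparation=preparation)


def write_label_mask(mask, image_path):
    """Write a :class:`LabelMask` as an 8-bit TIFF or PNG (bit-exact round trip)."""
    path = Path(image_path)
    data = mask.classes.astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(str(path), data)
    else:
        from PIL import Image

        Image.fromarray(data).save(path)


# ---------------------------------------------------------------------------
# Run configuration and logging
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Resolved configuration for a full analysis run.

    Defaults mirror the study conditions: the three-shell diameter protocol,
    coverage/eccentricity exclusion thresholds per preparation, the 0.1 µm
    dMRI discard threshold, the g-ratio group mean 0.64 and tract length
    11.47 mm, and SNR 50 for simulations.
    """

    seed: int = 0
    out_dir: str = "."
    # dMRI fitting
    d0: float = 0.45           # intrinsic intra-axonal diffusivity, µm²/ms
    # (ex vivo fixed tissue at room temperature; in vivo values are ~2-3x higher)
    d0_policy: str = "fixed"   # "fixed" (use `d0`) or "dti" (tensor fit per brain)
    snr: float = 50.0
    discard_um: float = 0.1    # diameter estimates below this are discarded
    # EM morphometry exclusion thresholds: preparation -> (min coverage, max ecc)
    coverage_min: dict = field(default_factory=lambda: {"epon": 0.95, "cryo": 0.85})
    eccentricity_max: dict = field(default_factory=lambda: {"epon": 0.92, "cryo": 0.975})
    min_area_px: int = 10
    # KDE
    kde_bandwidth: str = "silverman"
    kde_grid: int = 512
    # structure-function
    g_ratio: float = 0.64
    tract_length_mm: float = 11.47

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def digest(self):
        """Stable hash of the resolved configuration (provenance)."""
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def uniform_directions(n):
    """``n`` approximately uniformly distributed unit vectors (Fibonacci sphere).

    Deterministic; used both as a synthetic gradient scheme and as the
    direction set whose arithmetic mean realizes the powder average.
    """
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + 5.0**0.5) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def setup_logging(out_dir=None, seed=None, level=logging.INFO):
    """Configure the package logger; optionally tee to ``out_dir/axonsf.log``."""
    log.setLevel(level)
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers):
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        log.addHandler(handler)
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(Path(out_dir) / "axonsf.log")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(fh)
    if seed is not None:
        log.info("run seed: %d", seed)
    return log
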