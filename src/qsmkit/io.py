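"""Core data containers, NIfTI I/O, and phase scaling conventions.

Scanner phase images come in vendor-specific integer ranges and sign
conventions.  Everything downstream assumes phase in radians in the
half-open interval [-pi, pi), with positive phase evolution for
paramagnetic (positive-susceptibility) tissue.  This module is the only
place where those conventions are enforced.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "AcquisitionMeta",
    "MultiEchoDataset",
    "PipelineConfig",
    "load_multiecho",
    "load_sidecar",
    "rescale_phase",
    "wrap_phase",
    "write_volume",
    "read_volume",
]

# Relative tolerance for declaring echo spacing uniform.
_UNIFORM_SPACING_RTOL = 1e-3


def wrap_phase(phase: np.ndarray) -> np.ndarray:
    """Wrap angles into the half-open interval [-pi, pi)."""
    return np.mod(np.asarray(phase) + np.pi, 2.0 * np.pi) - np.pi


@dataclass
class AcquisitionMeta:
    """Acquisition metadata required by the reconstruction chain.

    Parameters mirror the essential reporting items of the consensus
    sequence table: field strength (T), echo times (s), repetition time
    (s), flip angle (deg), voxel size (mm), main-field direction in image
    axes, and the vendor phase-sign convention.
    """

    field_strength: float
    te_list: tuple
    tr: float
    flip_angle: float
    voxel_size: tuple
    b0_direction: tuple = (0.0, 0.0, 1.0)
    phase_sign: int = 1
    vendor: str = ""
    model: str = ""
    software: str = ""

    def __post_init__(self):
        self.te_list = tuple(float(t) for t in self.te_list)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if self.field_strength <= 0:
            raise ValueError("field_strength must be positive")
        if len(self.te_list) == 0:
            raise ValueError("te_list must contain at least one echo time")
        if any(b >= a for a, b in zip(self.te_list[1:], self.te_list[:-1])):
            raise ValueError("te_list must be strictly increasing")
        b0 = np.asarray(self.b0_direction, dtype=float)
        nrm = np.linalg.norm(b0)
        if abs(nrm - 1.0) > 1e-6:
            if nrm == 0:
                raise ValueError("b0_direction must have unit norm")
            b0 = b0 / nrm
        self.b0_direction = tuple(b0)
        if self.phase_sign not in (1, -1):
            raise ValueError("phase_sign must be +1 or -1")

    @property
    def n_echoes(self) -> int:
        return len(self.te_list)

    @property
    def delta_te(self) -> float:
        """Mean echo spacing in seconds (exact when spacing is uniform)."""
        if self.n_echoes < 2:
            raise ValueError("delta_te undefined for a single echo")
        return float(np.mean(np.diff(self.te_list)))

    @property
    def uniform_spacing(self) -> bool:
        if self.n_echoes < 3:
            return True
        d = np.diff(self.te_list)
        return bool(np.all(np.abs(d - d[0]) <= _UNIFORM_SPACING_RTOL * d[0]))


@dataclass
class MultiEchoDataset:
    """Per-echo magnitude and phase volumes plus acquisition metadata.

    ``magnitude`` and ``phase`` are arrays of shape ``(n_echoes, nx, ny, nz)``;
    phase is stored in radians within [-pi, pi).
    """

    magnitude: np.ndarray
    phase: np.ndarray
    meta: AcquisitionMeta
    affine: np.ndarray = None
    warnings_list: list = field(default_factory=list)

    def __post_init__(self):
        self.magnitude = np.asarray(self.magnitude, dtype=np.float64)
        self.phase = np.asarray(self.phase, dtype=np.float64)
        if self.magnitude.shape != self.phase.shape:
            raise ValueError("magnitude and phase must share one grid shape")
        if self.magnitude.ndim != 4:
            raise ValueError("expected (n_echoes, nx, ny, nz) arrays")
        if self.magnitude.shape[0] != self.meta.n_echoes:
            raise ValueError(
                f"echo-count mismatch: {self.magnitude.shape[0]} volumes vs "
                f"{self.meta.n_echoes} echo times"
            )
        if np.any(self.magnitude < 0):
            raise ValueError("magnitude must be nonnegative")
        if np.any(self.phase < -np.pi) or np.any(self.phase >= np.pi):
            raise ValueError("phase must lie in [-pi, pi)")
        if self.affine is None:
            self.affine = np.diag(list(self.meta.voxel_size) + [1.0])
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def n_echoes(self) -> int:
        return self.magnitude.shape[0]

    @property
    def shape(self) -> tuple:
        return self.magnitude.shape[1:]

    def complex_signal(self) -> np.ndarray:
        return self.magnitude * np.exp(1j * self.phase)


@dataclass
class PipelineConfig:
    """Every tunable of the reconstruction chain, with defaults.

    Serializes to a flat JSON/YAML mapping so the exact parameterization can
    be echoed into the provenance report, including defaults.
    """

    # echo combination
    fieldmap_method: str = "nlfit"          # nlfit | weighted
    nlfit_max_iter: int = 30
    nlfit_rtol: float = 1e-10
    weight_scheme: str = "te_m2"            # te_m2 | magnitude
    # masking
    mask_magnitude: str = "first"           # first | combined
    quality_factor: float = 1.0
    erosion_voxels: int = 1
    reintroduce_holes: bool = False
    # background removal
    bg_method: str = "vsharp"               # vsharp | pdf
    vsharp_radii_mm: tuple = tuple(float(r) for r in range(12, 0, -1))
    tsvd_threshold: float = 0.05
    pdf_tol: float = 1e-6
    pdf_max_iter: int = 200
    polynomial_detrend: bool = False
    # inversion
    inversion_method: str = "tv"            # tv | tkd
    tkd_threshold: float = 0.2
    lambda_reg: float = 0.0005
    mu_consistency: float = 0.05
    tv_max_iter: int = 100
    tv_rtol: float = 1e-3
    # referencing / QC
    reference_region: str = "wholebrain"
    qc_zscore: float = 3.0
    qc_abs_bound_ppm: float = 0.3
    qc_streak_ppm: float = 0.5
    qc_streak_fraction: float = 0.01
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["vsharp_radii_mm"] = list(self.vsharp_radii_mm)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "vsharp_radii_mm" in d:
            d["vsharp_radii_mm"] = tuple(d["vsharp_radii_mm"])
        return cls(**d)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# Phase scaling
# ---------------------------------------------------------------------------

def rescale_phase(raw, stored_min, stored_max, phase_sign=1):
    """Map stored phase values onto radians in [-pi, pi).

    The affine map sends ``stored_min`` to ``-pi`` and ``stored_min + range``
    to ``+pi`` half-open.  For integer-quantized ranges the divisor is
    ``range + 1`` quantization step, which avoids assigning both ends of the
    integer range to the same +-pi bin.  The result is multiplied by
    ``phase_sign`` and re-wrapped so the output is strictly within [-pi, pi).
    """
    raw = np.asarray(raw, dtype=np.float64)
    stored_min = float(stored_min)
    stored_max = float(stored_max)
    if stored_max <= stored_min:
        raise ValueError("degenerate phase range: stored_max must exceed stored_min")
    if phase_sign not in (1, -1):
        raise ValueError("phase_sign must be +1 or -1")
    span = stored_max - stored_min
    # one quantization step for integer-valued ranges, zero otherwise
    if float(stored_min).is_integer() and float(stored_max).is_integer():
        span += 1.0
    phase = -np.pi + 2.0 * np.pi * (raw - stored_min) / span
    return wrap_phase(phase_sign * phase)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

_REQUIRED_SIDECAR = {
    "EchoTimes_s": "te_list",
    "RepetitionTime_s": "tr",
    "FlipAngle_deg": "flip_angle",
    "FieldStrength_T": "field_strength",
}


def load_sidecar(path) -> AcquisitionMeta:
    """Read a flat JSON metadata sidecar into :class:`AcquisitionMeta`."""
    with open(path) as fh:
        raw = json.load(fh)
    kwargs = {}
    for key, attr in _REQUIRED_SIDECAR.items():
        if key not in raw:
            raise ValueError(f"sidecar missing required metadata field: {key}")
        kwargs[attr] = raw[key]
    kwargs["voxel_size"] = tuple(raw.get("VoxelSize_mm", (1.0, 1.0, 1.0)))
    kwargs["b0_direction"] = tuple(raw.get("B0Direction", (0.0, 0.0, 1.0)))
    kwargs["phase_sign"] = int(raw.get("PhaseSign", 1))
    kwargs["vendor"] = raw.get("Vendor", "")
    kwargs["model"] = raw.get("ScannerModel", "")
    kwargs["software"] = raw.get("SoftwareRelease", "")
    return AcquisitionMeta(**kwargs)


def meta_to_sidecar(meta: AcquisitionMeta) -> dict:
    return {
        "EchoTimes_s": list(meta.te_list),
        "RepetitionTime_s": meta.tr,
        "FlipAngle_deg": meta.flip_angle,
        "FieldStrength_T": meta.field_strength,
        "VoxelSize_mm": list(meta.voxel_size),
        "B0Direction": list(meta.b0_direction),
        "PhaseSign": meta.phase_sign,
        "Vendor": meta.vendor,
        "ScannerModel": meta.model,
        "SoftwareRelease": meta.software,
    }


def read_volume(path):
    """Read one NIfTI volume; returns (float64 array, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=np.float64), img.affine


def write_volume(volume, meta_or_affine, path):
    """Write one volume as NIfTI-1 with voxel size/orientation in the affine."""
    volume = np.asarray(volume)
    if isinstance(meta_or_affine, AcquisitionMeta):
        affine = np.diag(list(meta_or_affine.voxel_size) + [1.0])
    else:
        affine = np.asarray(meta_or_affine, dtype=float)
    img = nib.Nifti1Image(volume.astype(np.float32, copy=False), affine)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def load_multiecho(magnitude_paths: Sequence, phase_paths: Sequence,
                   sidecar_path, phase_range=None) -> MultiEchoDataset:
    """Assemble a :class:`MultiEchoDataset` from per-echo NIfTI files.

    ``phase_range`` is an optional ``(stored_min, stored_max)`` pair for
    integer-stored phase; when omitted the phase files must already contain
    radians in [-pi, pi) (up to the vendor sign flip from the sidecar).
    """
    magnitude_paths = list(magnitude_paths)
    phase_paths = list(phase_paths)
    if len(magnitude_paths) != len(phase_paths):
        raise ValueError(
            f"echo-count mismatch: {len(magnitude_paths)} magnitude vs "
            f"{len(phase_paths)} phase files"
        )
    meta = load_sidecar(sidecar_path)
    if meta.n_echoes != len(magnitude_paths):
        raise ValueError(
            f"echo-count mismatch: sidecar lists {meta.n_echoes} echo times "
            f"but {len(magnitude_paths)} volumes were given"
        )
    mags, phases = [], []
    affine = None
    for mp, pp in zip(magnitude_paths, phase_paths):
        m, aff = read_volume(mp)
        p, _ = read_volume(pp)
        if affine is None:
            affine = aff
        mags.append(m)
        if phase_range is not None:
            p = rescale_phase(p, phase_range[0], phase_range[1], meta.phase_sign)
        else:
            p = wrap_phase(meta.phase_sign * p)
        phases.append(p)
    warns = []
    if not meta.uniform_spacing:
        msg = "echo spacing is not uniform; weighted echo combination assumes it"
        warns.append(msg)
        warnings.warn(msg)
    # b0 direction from the image orientation: slice-normal column of the
    # affine, normalized (main field along the scanner z axis).
    rot = np.asarray(affine)[:3, :3]
    b0_img = np.linalg.inv(rot) @ np.array([0.0, 0.0, 1.0])
    b0_img = b0_img / np.linalg.norm(b0_img)
    meta.b0_direction = tuple(b0_img)
    return MultiEchoDataset(
        magnitude=np.stack(mags), phase=np.stack(phases), meta=meta,
        affine=affine, warnings_list=warns,
    )
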