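"""Referencing, ROI statistics and quality-control screening.

Susceptibility from phase is only determined up to an additive constant, so
maps must be referenced to an internal region (whole brain or CSF are
common) before any analysis; differences between ROI means are invariant to
that choice.  ROI statistics are restricted to the map's valid mask so that
zero-filled invalid voxels never bias means.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .inversion import SusceptibilityMap

__all__ = [
    "RoiDefinition",
    "RoiReport",
    "reference_map",
    "rereference_value",
    "roi_stats",
    "qc_screen",
]


@dataclass
class RoiDefinition:
    """A labelled binary region used as analysis target or reference."""

    label: str
    mask: np.ndarray
    role: str = "target"     # target | reference

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class RoiReport:
    """Per-ROI mean/std/count (ppm) plus exclusion bookkeeping."""

    rows: list = field(default_factory=list)
    reference_region: str = ""
    excluded: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows,
            columns=["label", "mean_ppm", "std_ppm", "n_voxels",
                     "n_excluded"])

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)


def reference_map(chi: SusceptibilityMap,
                  region: RoiDefinition) -> SusceptibilityMap:
    """Subtract the mean over (region & valid_mask) from all valid voxels."""
    sel = region.mask & chi.valid_mask
    if not sel.any():
        raise ValueError(
            f"reference region '{region.label}' does not intersect the "
            "valid mask")
    mean = float(chi.chi[sel].mean())
    new_chi = np.where(chi.valid_mask, chi.chi - mean, 0.0)
    return replace(chi, chi=new_chi, reference_region=region.label)


def rereference_value(roi_value_oldref, newref_mean_oldref):
    """Re-express an ROI susceptibility relative to a new reference region.

    Both inputs must be on the same (old-reference) scale; the result is
    exact linear arithmetic, e.g. an ROI at 0.010 ppm on a whole-brain
    reference becomes 0.008 ppm on a CSF reference whose mean is 0.002 ppm
    above whole brain.
    """
    out = np.asarray(roi_value_oldref, dtype=float) - \
        np.asarray(newref_mean_oldref, dtype=float)
    if not np.all(np.isfinite(out)):
        raise ValueError("inputs must be finite")
    return float(out) if out.ndim == 0 else out


def roi_stats(chi: SusceptibilityMap,
              rois: Sequence[RoiDefinition]) -> RoiReport:
    """Mean, standard deviation and voxel count per ROI, valid voxels only.

    Requires a referenced map (reference susceptibility maps to an internal
    region before analysis).  ROIs falling entirely outside the valid mask
    are reported as excluded rather than as zero.
    """
    if not chi.is_referenced:
        raise ValueError(
            "susceptibility map is not referenced; always reference maps to "
            "an internal region before further analyses (reference_map)")
    report = RoiReport(reference_region=chi.reference_region or "")
    for roi in rois:
        sel = roi.mask & chi.valid_mask
        n_excl = int(roi.mask.sum() - sel.sum())
        if not sel.any():
            report.excluded.append(roi.label)
            continue
        vals = chi.chi[sel]
        report.rows.append([roi.label, float(vals.mean()),
                            float(vals.std(ddof=0)), int(sel.sum()), n_excl])
    return report


def qc_screen(chi: SusceptibilityMap, rois: Sequence[RoiDefinition] = (),
              cohort_means=None, zscore=3.0, abs_bound_ppm=0.3,
              streak_ppm=0.5, streak_fraction=0.01) -> dict:
    """Heuristic screening for common reconstruction faults.

    Returns a dict of flags (never raises):

    * ``roi_outlier`` — an ROI mean beyond ``abs_bound_ppm`` in magnitude,
      or beyond ``zscore`` standard deviations of a supplied cohort of ROI
      means (cohort screening needs >= 5 subjects);
    * ``zero_spike`` — a spike of exactly-zero voxels inside the valid mask
      (a masking fault: zero-filled voxels leaked into the map);
    * ``streaking`` — more than ``streak_fraction`` of valid voxels with
      ``|chi|`` above ``streak_ppm``.
    """
    flags = {"roi_outlier": False, "zero_spike": False, "streaking": False,
             "details": []}
    valid_vals = chi.chi[chi.valid_mask]
    if valid_vals.size:
        zero_frac = float(np.mean(valid_vals == 0.0))
        if zero_frac > 0.01:
            flags["zero_spike"] = True
            flags["details"].append(
                f"{zero_frac:.1%} of valid voxels are exactly zero")
        streak = float(np.mean(np.abs(valid_vals) > streak_ppm))
        if streak > streak_fraction:
            flags["streaking"] = True
            flags["details"].append(
                f"{streak:.1%} of valid voxels exceed |{streak_ppm}| ppm")
    for roi in rois:
        sel = roi.mask & chi.valid_mask
        if not sel.any():
            continue
        m = float(chi.chi[sel].mean())
        if abs(m) > abs_bound_ppm:
            flags["roi_outlier"] = True
            flags["details"].append(
                f"ROI '{roi.label}' mean {m:+.3f} ppm beyond "
                f"+-{abs_bound_ppm} ppm")
        if cohort_means is not None and roi.label in cohort_means:
            cohort = np.asarray(cohort_means[roi.label], dtype=float)
            if cohort.size >= 5 and cohort.std() > 0:
                z = (m - cohort.mean()) / cohort.std()
                if abs(z) > zscore:
                    flags["roi_outlier"] = True
                    flags["details"].append(
                        f"ROI '{roi.label}' z-score {z:+.1f} beyond "
                        f"+-{zscore}")
    return flags
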