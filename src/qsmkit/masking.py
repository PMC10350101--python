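"""Four-stage mask workflow for background removal, inversion and display.

Mask 1: initial brain mask from a magnitude image (built-in thresholding or
an external brain-extraction tool).  Mask 2: reliable-phase mask from the
inverse noise map thresholded at (a factor times) its FOV mean.  Mask 3:
their intersection with interior holes filled — the input to background
field removal.  Mask 4: Mask 3 eroded for dipole inversion, optionally with
the unreliable-phase holes reintroduced (excluded) to limit streaking from
bad phase inside the brain; the display mask is the eroded mask with holes
filled.  All operations are deterministic.
"""

from __future__ import annotations

import subprocess
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import ball

__all__ = [
    "MaskSet",
    "initial_brain_mask",
    "reliable_phase_mask",
    "finalize_masks",
]

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class MaskSet:
    """The four masks plus the record of excluded interior holes."""

    mask1: np.ndarray   # initial brain
    mask2: np.ndarray   # reliable phase
    mask3: np.ndarray   # filled, for background removal
    mask4: np.ndarray   # eroded, for dipole inversion
    display_mask: np.ndarray  # eroded with holes filled, for display/reporting
    holes: np.ndarray   # interior cavities of mask1 & mask2
    erosion_voxels: int = 0

    def __post_init__(self):
        for name in ("mask1", "mask2", "mask3", "mask4", "display_mask",
                     "holes"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        if self.mask1.shape != self.mask3.shape or \
                self.mask3.shape != self.mask4.shape:
            raise ValueError("all masks must share one grid shape")
        if np.any(self.mask4 & ~self.mask3):
            raise ValueError("mask4 must be a subset of mask3")


def initial_brain_mask(magnitude, method="threshold", external_cmd=None):
    """Initial brain mask (Mask 1) from a magnitude image.

    The built-in method is deliberately simple: Otsu threshold, largest
    6-connected component, morphological closing with a radius-2 ball.  For
    real data a dedicated brain-extraction tool is preferable; pass
    ``method="external"`` with a shell command containing ``{in}`` and
    ``{out}`` placeholders for NIfTI paths.
    """
    magnitude = np.asarray(magnitude, dtype=np.float64)
    if np.any(magnitude < 0):
        raise ValueError("magnitude must be nonnegative")
    if method == "external":
        return _external_brain_mask(magnitude, external_cmd)
    if method != "threshold":
        raise ValueError(f"unknown method: {method}")
    if not np.any(magnitude > 0):
        raise ValueError(
            "magnitude image is empty; cannot build a brain mask "
            "(adjust the threshold or supply an external mask)")
    if magnitude.min() == magnitude.max():
        raise ValueError("constant magnitude image; cannot threshold")
    thr = threshold_otsu(magnitude)
    raw = magnitude > thr
    if not raw.any():
        raise ValueError(
            "thresholding produced an empty mask; adjust the threshold")
    labels, n = ndimage.label(raw, structure=_STRUCT6)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=np.arange(1, n + 1))
        raw = labels == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_closing(raw, structure=ball(2))
    # closing can clip at the array border; keep the original where it did
    mask |= raw
    if not mask.any():
        raise ValueError("brain mask is empty; adjust the threshold")
    return mask


def _external_brain_mask(magnitude, external_cmd):
    """Shell out to a user-supplied brain-extraction command."""
    import tempfile
    from pathlib import Path

    import nibabel as nib

    if not external_cmd:
        raise ValueError("external method requires external_cmd")
    with tempfile.TemporaryDirectory() as td:
        inp = Path(td) / "magnitude.nii.gz"
        outp = Path(td) / "mask.nii.gz"
        nib.save(nib.Nifti1Image(magnitude.astype(np.float32), np.eye(4)),
                 str(inp))
        cmd = external_cmd.format(**{"in": str(inp), "out": str(outp)})
        subprocess.run(cmd, shell=True, check=True)
        mask = np.asarray(nib.load(str(outp)).get_fdata()) > 0.5
    if not mask.any():
        raise ValueError("external tool returned an empty mask")
    return mask


def reliable_phase_mask(noise_or_quality, factor=1.0, is_noise=False):
    """Reliable-phase mask (Mask 2): threshold the inverse noise map.

    Keeps voxels where the reliability map (inverse noise, or a quality map
    passed directly) is at least ``factor`` times its mean over the whole
    FOV; the distribution is typically bimodal, so the mean separates
    reliable from unreliable voxels.  ``factor=1.2`` is a common stricter
    choice.
    """
    m = np.asarray(noise_or_quality, dtype=np.float64)
    if not np.all(np.isfinite(m)):
        raise ValueError("reliability map must be finite over the FOV")
    if is_noise:
        with np.errstate(divide="ignore"):
            m = np.where(m > 0, 1.0 / m, 0.0)
            finite = m[np.isfinite(m)]
            m = np.where(np.isfinite(m), m,
                         finite.max() if finite.size else 0.0)
    mean = m.mean()
    if np.allclose(m, m.flat[0]):
        warnings.warn("constant reliability map; keeping every voxel")
        return np.ones(m.shape, dtype=bool)
    return m >= factor * mean


def fill_holes(mask):
    """Fill interior cavities: background components (6-connectivity) that do
    not touch the volume border."""
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(~mask, structure=_STRUCT6)
    if n == 0:
        return mask.copy()
    border_labels = set()
    for axis in range(3):
        for sl in (0, -1):
            face = np.take(labels, sl, axis=axis)
            border_labels.update(np.unique(face[face > 0]))
    holes = (labels > 0) & ~np.isin(labels, sorted(border_labels))
    return mask | holes


def finalize_masks(mask1, mask2, erosion_voxels=1,
                   reintroduce_holes=False) -> MaskSet:
    """Combine Masks 1 and 2 into the background-removal, inversion and
    display masks.

    ``mask3`` is the hole-filled intersection; ``mask4`` is ``mask3`` eroded
    by ``erosion_voxels`` (6-connected structuring element per voxel), minus
    the holes when ``reintroduce_holes`` is set; the display mask is the
    eroded mask with holes filled.
    """
    mask1 = np.asarray(mask1, dtype=bool)
    mask2 = np.asarray(mask2, dtype=bool)
    if mask1.shape != mask2.shape:
        raise ValueError("mask shapes differ")
    if erosion_voxels < 0:
        raise ValueError("erosion_voxels must be >= 0")
    intersect = mask1 & mask2
    filled = fill_holes(intersect)
    holes = filled & ~intersect
    mask3 = filled
    if not mask3.any():
        raise ValueError("mask3 is empty after combining masks 1 and 2")
    if erosion_voxels > 0:
        eroded = ndimage.binary_erosion(mask3, structure=_STRUCT6,
                                        iterations=erosion_voxels)
    else:
        eroded = mask3.copy()
    display = eroded.copy()
    mask4 = eroded & ~holes if reintroduce_holes else eroded
    return MaskSet(mask1=mask1, mask2=mask2, mask3=mask3, mask4=mask4,
                   display_mask=display, holes=holes,
                   erosion_voxels=int(erosion_voxels))
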