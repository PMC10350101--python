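"""Background-field removal inside the brain mask.

The field measured in the brain is the sum of the tissue field (sources
inside the mask) and a background field from outside sources — dominated by
the ~9 ppm tissue/air susceptibility difference — which is harmonic inside
the mask.  Two removal methods are provided:

* V-SHARP: spherical-mean-value (SMV) filtering.  The mean of a harmonic
  function over any sphere inside the region equals its center value, so
  ``(delta - SMV) * field`` annihilates the background part.  Applying the
  filter with progressively smaller radii toward the mask boundary limits
  erosion to about one voxel; the filtered field is then deconvolved by
  truncated-threshold inversion of ``(delta - SMV)`` at the largest radius.
* PDF: projection onto dipole fields.  An effective susceptibility
  distribution supported outside the mask is fitted, by noise-weighted
  linear least squares, to mimic the in-mask field; its induced field is
  subtracted.

Both methods are linear in the input field.  V-SHARP also removes the
constant (k=0) component, so its output has approximately zero mean over
the valid mask — the implicit whole-brain referencing some pipelines rely
on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as spfft
from scipy.sparse.linalg import LinearOperator, cg

from .inversion import DipoleKernel, dipole_kernel

__all__ = [
    "TissueFieldResult",
    "smv_kernel",
    "vsharp",
    "pdf",
    "polynomial_detrend",
]


@dataclass
class TissueFieldResult:
    """Tissue field (Hz) with its validity mask and a method record."""

    tissue_field: np.ndarray
    valid_mask: np.ndarray
    method: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        self.tissue_field = np.where(self.valid_mask,
                                     np.asarray(self.tissue_field,
                                                dtype=np.float64), 0.0)


def smv_kernel(radius_mm, voxel_size, grid_shape):
    """Normalized spherical-mean-value kernel and its Fourier transform.

    The spatial kernel is uniform over the discretized sphere of the given
    radius (voxel centers within ``radius_mm``), coefficients summing to 1,
    centered at index 0 with wraparound so that its DFT is real.
    Returns ``(spatial, k_space)``.
    """
    voxel_size = tuple(float(v) for v in voxel_size)
    if radius_mm < max(voxel_size):
        raise ValueError(
            f"SMV radius {radius_mm} mm is smaller than a voxel "
            f"{max(voxel_size)} mm")
    axes = []
    for n, dv in zip(grid_shape, voxel_size):
        c = np.arange(n, dtype=float)
        c[c > n // 2] -= n          # centered-at-origin with wraparound
        axes.append(c * dv)
    X, Y, Z = np.meshgrid(*axes, indexing="ij", sparse=True)
    inside = (X ** 2 + Y ** 2 + Z ** 2) <= radius_mm ** 2
    kernel = inside.astype(np.float64)
    kernel /= kernel.sum()
    return kernel, spfft.fftn(kernel).real


def _fit_mask(mask, rho_k, tol=1e-3):
    """Voxels whose SMV sphere lies entirely inside ``mask``."""
    frac = spfft.ifftn(spfft.fftn(mask.astype(np.float64)) * rho_k).real
    return mask & (frac >= 1.0 - tol)


def vsharp(total_field, mask3, radii_mm=None, tsvd_threshold=0.05,
           voxel_size=(1.0, 1.0, 1.0)) -> TissueFieldResult:
    """Variable-radius SHARP background removal.

    For every voxel the largest radius whose sphere fits inside the mask is
    used for the ``(delta - SMV)`` high-pass; the composite is deconvolved
    with the largest radius by thresholded inversion (frequencies where
    ``|1 - SMV_k| < tsvd_threshold`` are zeroed).  The valid mask excludes
    voxels where no radius fits, i.e. roughly a one-voxel erosion at the
    smallest radius.
    """
    total_field = np.asarray(total_field, dtype=np.float64)
    mask3 = np.asarray(mask3, dtype=bool)
    if radii_mm is None:
        radii_mm = [float(r) for r in range(12, 0, -1)]
    radii = [float(r) for r in radii_mm]
    if any(b >= a for a, b in zip(radii, radii[1:])):
        raise ValueError("radii_mm must be strictly descending")
    f_masked = np.where(mask3, total_field, 0.0)
    fk = spfft.fftn(f_masked)

    highpass = np.zeros_like(total_field)
    assigned = np.zeros(total_field.shape, dtype=bool)
    valid_mask = None
    rho_largest = None
    # ascending radii so that larger radii overwrite where their sphere fits
    for r in sorted(radii):
        _, rho_k = smv_kernel(r, voxel_size, total_field.shape)
        fit = _fit_mask(mask3, rho_k)
        if valid_mask is None:
            valid_mask = fit                      # smallest radius
        if r == max(radii):
            rho_largest = rho_k
        if not fit.any():
            continue
        h = f_masked - spfft.ifftn(fk * rho_k).real
        highpass[fit] = h[fit]
        assigned |= fit
    if valid_mask is None or not valid_mask.any():
        raise ValueError(
            "mask too small: no voxel admits even the smallest SMV radius")

    inv = 1.0 - rho_largest
    inv_op = np.where(np.abs(inv) >= tsvd_threshold, 1.0 / np.where(
        inv == 0, 1.0, inv), 0.0)
    tissue = spfft.ifftn(spfft.fftn(np.where(valid_mask, highpass, 0.0))
                         * inv_op).real
    return TissueFieldResult(
        tissue_field=tissue, valid_mask=valid_mask, method="vsharp",
        params={"radii_mm": radii, "tsvd_threshold": tsvd_threshold})


def pdf(total_field, mask3, noise_weight=None, b0_direction=(0.0, 0.0, 1.0),
        voxel_size=(1.0, 1.0, 1.0), tol=1e-6, max_iter=200,
        kernel: DipoleKernel | None = None) -> TissueFieldResult:
    """Projection onto dipole fields.

    Solves ``min_xb || W (f - D xb) ||_2`` over effective sources ``xb``
    supported outside the mask (W = noise weight inside the mask, 0
    outside) by conjugate gradients on the normal equations, then subtracts
    the fitted background field inside the mask.
    """
    total_field = np.asarray(total_field, dtype=np.float64)
    mask3 = np.asarray(mask3, dtype=bool)
    if not mask3.any():
        raise ValueError("mask3 is empty")
    if noise_weight is None:
        W = mask3.astype(np.float64)
    else:
        W = np.asarray(noise_weight, dtype=np.float64)
        if np.any(W < 0):
            raise ValueError("noise_weight must be nonnegative")
        W = np.where(mask3, W, 0.0)
        if not np.any(W > 0):
            W = mask3.astype(np.float64)
    if kernel is None:
        kernel = dipole_kernel(total_field.shape, voxel_size, b0_direction)
    D = kernel.values
    outside = ~mask3
    shape = total_field.shape
    W2 = W ** 2

    def dconv(x):
        return spfft.ifftn(D * spfft.fftn(x)).real

    def normal_op(xf):
        x = xf.reshape(shape)
        ax = W2 * dconv(np.where(outside, x, 0.0))
        return np.where(outside, dconv(ax), 0.0).ravel()

    n = total_field.size
    op = LinearOperator((n, n), matvec=normal_op, dtype=np.float64)
    rhs = np.where(outside, dconv(W2 * np.where(mask3, total_field, 0.0)),
                   0.0).ravel()
    xb, info = cg(op, rhs, rtol=tol, maxiter=max_iter)
    if info > 0:
        warnings.warn(
            f"PDF conjugate-gradient solver did not reach tolerance {tol} "
            f"within {max_iter} iterations; returning the best iterate")
    xb = np.where(outside, xb.reshape(shape), 0.0)
    background = dconv(xb)
    tissue = np.where(mask3, total_field - background, 0.0)
    return TissueFieldResult(
        tissue_field=tissue, valid_mask=mask3, method="pdf",
        params={"tol": tol, "max_iter": max_iter, "cg_info": int(info)})


def polynomial_detrend(field, mask, order=2):
    """Remove a low-order 3D polynomial trend inside the mask (optional
    post-processing; V-SHARP and PDF typically do not need it)."""
    field = np.asarray(field, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    coords = np.meshgrid(*[np.linspace(-1, 1, n) for n in field.shape],
                         indexing="ij")
    terms = [np.ones_like(field)]
    if order >= 1:
        terms += list(coords)
    if order >= 2:
        terms += [c1 * c2 for i, c1 in enumerate(coords)
                  for c2 in coords[i:]]
    A = np.stack([t[mask] for t in terms], axis=1)
    coef, *_ = np.linalg.lstsq(A, field[mask], rcond=None)
    trend = sum(c * t for c, t in zip(coef, terms))
    return np.where(mask, field - trend, 0.0)
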