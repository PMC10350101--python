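"""Total-field estimation from multi-echo phase.

Two echo-combination routes are provided, matching common practice:

* nonlinear complex fitting of ``M(TE) exp(i(2 pi f TE + phi0))`` over all
  echoes (requires >= 3 echoes), which resolves wraps in the temporal
  dimension and yields a per-voxel noise map; the fitted field is a
  principal value within +-1/(2 dTE) and still needs *spatial* unwrapping;
* weighted echo averaging of spatially unwrapped per-echo phase after
  explicit phase-offset removal, which gives higher field SNR when the TE
  range is well matched to tissue T2*.

Spatial unwrapping is an exact, path-based region-growing method ordered by
descending quality: the output differs from the input by an integer
multiple of 2 pi at every voxel.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import MultiEchoDataset, wrap_phase

__all__ = [
    "TotalFieldResult",
    "fit_complex_multiecho",
    "unwrap_spatial",
    "template_unwrap_echoes",
    "combine_weighted_average",
    "nlfit_unwrapped_field",
]


@dataclass
class TotalFieldResult:
    """Voxelwise field shift with offset, uncertainty and reliability maps."""

    field: np.ndarray     # Hz
    phi0: np.ndarray      # radians in [-pi, pi)
    noise: np.ndarray     # field-uncertainty, arbitrary consistent units
    quality: np.ndarray   # reliability in [0, 1]
    method: str = ""

    def __post_init__(self):
        if np.any(self.noise < 0):
            raise ValueError("noise map must be nonnegative")
        if np.any((self.quality < 0) | (self.quality > 1)):
            raise ValueError("quality map must lie in [0, 1]")


def _quality_from_noise(noise):
    """Min-max normalize the inverse noise map into [0, 1] over the FOV."""
    with np.errstate(divide="ignore"):
        inv = np.where(noise > 0, 1.0 / noise, 0.0)
    finite = inv[np.isfinite(inv)]
    lo, hi = (finite.min(), finite.max()) if finite.size else (0.0, 1.0)
    if hi <= lo:
        return np.ones_like(inv)
    q = (inv - lo) / (hi - lo)
    return np.clip(q, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Nonlinear complex multi-echo fitting
# ---------------------------------------------------------------------------

def fit_complex_multiecho(data: MultiEchoDataset, max_iter=30,
                          rtol=1e-10) -> TotalFieldResult:
    """Per-voxel least-squares fit of the complex multi-echo signal model.

    Initialization is a magnitude-weighted average of consecutive-echo phase
    differences (Hermitian products), refined by Gauss-Newton steps on the
    wrapped phase residuals with weights M_e^2.  For uniform echo spacing
    the returned field is the principal value within +-1/(2 dTE); spatial
    unwrapping must follow.  The noise map is the square root of the
    field-parameter variance from the fit's normal equations; quality is
    its min-max-normalized inverse.
    """
    if data.n_echoes < 3:
        raise ValueError(
            "nonlinear complex fitting requires >= 3 echoes; use the "
            "weighted-averaging path (combine_weighted_average) instead")
    te = np.asarray(data.meta.te_list)          # (E,)
    M = data.magnitude                           # (E, ...)
    S = data.complex_signal()
    w = M ** 2

    # init: f from Hermitian inter-echo products, weighted by |S_e||S_e+1|
    num = np.zeros(data.shape)
    den = np.zeros(data.shape)
    for j in range(data.n_echoes - 1):
        prod = S[j + 1] * np.conj(S[j])
        u = np.abs(prod)
        dphi = np.angle(prod)
        dt = te[j + 1] - te[j]
        num += u * dphi / (2.0 * np.pi * dt)
        den += u
    with np.errstate(invalid="ignore"):
        f = np.where(den > 0, num / den, 0.0)
    # init phi0 as the weighted mean residual phase after demodulation
    acc = np.zeros(data.shape, dtype=complex)
    for e in range(data.n_echoes):
        acc += S[e] * np.exp(-2j * np.pi * f * te[e])
    phi0 = np.angle(acc)

    # Gauss-Newton on wrapped residuals; 2x2 normal equations per voxel
    A = np.sum(w * (2.0 * np.pi * te[:, None, None, None]) ** 2, axis=0)
    B = np.sum(w * 2.0 * np.pi * te[:, None, None, None], axis=0)
    C = np.sum(w, axis=0)
    det = A * C - B ** 2
    ok = det > 0
    for _ in range(max_iter):
        b1 = np.zeros(data.shape)
        b2 = np.zeros(data.shape)
        for e in range(data.n_echoes):
            delta = wrap_phase(data.phase[e] - 2.0 * np.pi * f * te[e] - phi0)
            b1 += w[e] * 2.0 * np.pi * te[e] * delta
            b2 += w[e] * delta
        with np.errstate(invalid="ignore", divide="ignore"):
            df = np.where(ok, (C * b1 - B * b2) / det, 0.0)
            dphi0 = np.where(ok, (A * b2 - B * b1) / det, 0.0)
        f = f + df
        phi0 = phi0 + dphi0
        step = max(np.max(np.abs(df)) * 2.0 * np.pi * te[-1],
                   np.max(np.abs(dphi0)))
        if step < rtol:
            break
    f = np.where(ok, f, 0.0)
    phi0 = wrap_phase(np.where(ok, phi0, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        noise = np.where(ok, np.sqrt(np.where(ok, C / np.maximum(det, 1e-300),
                                              0.0)), np.inf)
    quality = _quality_from_noise(noise)
    quality = np.where(ok, quality, 0.0)
    noise = np.where(ok, noise, np.max(noise[ok]) if ok.any() else 1.0)
    return TotalFieldResult(field=f, phi0=phi0, noise=noise, quality=quality,
                            method="nlfit")


# ---------------------------------------------------------------------------
# Exact spatial unwrapping (quality-guided region growing)
# ---------------------------------------------------------------------------

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


def unwrap_spatial(wrapped, quality, mask):
    """Path-based region-growing phase unwrap, ordered by descending quality.

    Each voxel's output differs from its input by an integer multiple of
    2 pi (exactness).  Growth starts from the maximum-quality voxel of each
    connected mask component; ties break on voxel index, so the result is
    deterministic.  Disconnected components are internally consistent but
    carry unconstrained relative offsets (a warning reports their count).
    Voxels outside the mask are returned as 0.
    """
    wrapped = np.asarray(wrapped, dtype=np.float64)
    quality = np.asarray(quality, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if wrapped.shape != mask.shape or quality.shape != mask.shape:
        raise ValueError("wrapped, quality and mask must share one shape")

    labels, n_comp = ndimage.label(mask, structure=_STRUCT6)
    if n_comp > 1:
        warnings.warn(
            f"mask has {n_comp} disconnected components; their relative "
            "2*pi offsets are unconstrained")

    shape = mask.shape
    strides = (shape[1] * shape[2], shape[2], 1)
    wrapped_f = wrapped.ravel()
    quality_f = quality.ravel()
    mask_f = mask.ravel()
    out = np.zeros(wrapped_f.size)
    solved = np.zeros(wrapped_f.size, dtype=bool)
    two_pi = 2.0 * np.pi

    neighbor_offsets = [strides[0], -strides[0], strides[1], -strides[1], 1, -1]

    def neighbors(idx):
        i, rem = divmod(idx, strides[0])
        j, k = divmod(rem, strides[1])
        pos = (i, j, k)
        for a, off in ((0, strides[0]), (1, strides[1]), (2, 1)):
            if pos[a] + 1 < shape[a]:
                yield idx + off
            if pos[a] - 1 >= 0:
                yield idx - off

    for comp in range(1, n_comp + 1):
        comp_idx = np.flatnonzero((labels == comp).ravel())
        seed = comp_idx[np.argmax(quality_f[comp_idx])]
        out[seed] = wrapped_f[seed]
        solved[seed] = True
        heap = []
        for nb in neighbors(seed):
            if mask_f[nb] and not solved[nb]:
                heapq.heappush(heap, (-quality_f[nb], nb, out[seed]))
        while heap:
            negq, idx, ref = heapq.heappop(heap)
            if solved[idx]:
                continue
            val = wrapped_f[idx] + two_pi * np.round((ref - wrapped_f[idx])
                                                     / two_pi)
            out[idx] = val
            solved[idx] = True
            for nb in neighbors(idx):
                if mask_f[nb] and not solved[nb]:
                    heapq.heappush(heap, (-quality_f[nb], nb, val))
    return out.reshape(shape)


# ---------------------------------------------------------------------------
# Weighted echo averaging
# ---------------------------------------------------------------------------

def estimate_phi0_two_echo(unwrapped_phases, te):
    """Extrapolate the linear phase evolution of the first two echoes to TE=0."""
    p1, p2 = unwrapped_phases[0], unwrapped_phases[1]
    return p1 - te[0] * (p2 - p1) / (te[1] - te[0])


def template_unwrap_echoes(data: MultiEchoDataset, quality, mask):
    """Template unwrapping: spatially unwrap an early echo, predict the rest.

    The first echo is unwrapped spatially; the second is aligned to its
    linear TE scaling by per-voxel 2 pi rounding; remaining echoes are
    aligned to the two-echo linear prediction (offset + slope * TE), which
    tolerates a nonzero phase offset.  Returns an (E, ...) array, zero
    outside the mask.
    """
    te = np.asarray(data.meta.te_list)
    if data.n_echoes < 2:
        raise ValueError("template unwrapping requires >= 2 echoes")
    out = np.zeros_like(data.phase)
    out[0] = unwrap_spatial(data.phase[0], quality, mask)
    pred = out[0] * te[1] / te[0]
    out[1] = data.phase[1] + 2.0 * np.pi * np.round(
        (pred - data.phase[1]) / (2.0 * np.pi))
    if data.n_echoes > 2:
        slope = (out[1] - out[0]) / (te[1] - te[0])
        offset = out[0] - slope * te[0]
        for e in range(2, data.n_echoes):
            pred = offset + slope * te[e]
            out[e] = data.phase[e] + 2.0 * np.pi * np.round(
                (pred - data.phase[e]) / (2.0 * np.pi))
    return np.where(mask[None], out, 0.0)


def combine_weighted_average(data: MultiEchoDataset, unwrapped_phases,
                             phi0=None, weight_scheme="te_m2"
                             ) -> TotalFieldResult:
    """Weighted average of per-echo field estimates after offset removal.

    ``f = sum_e w_e (phi_e - phi0) / (2 pi TE_e) / sum_e w_e`` with default
    weights ``w_e = TE_e M_e^2`` (inverse phase-variance weighting under
    high-SNR complex Gaussian noise, scaled by TE); ``weight_scheme="magnitude"``
    uses M_e, ``"uniform"`` equal weights.  When ``phi0`` is not supplied it
    is extrapolated from the first two echoes to TE = 0.
    """
    if data.n_echoes < 2:
        raise ValueError("weighted echo averaging requires >= 2 echoes")
    te = np.asarray(data.meta.te_list)
    phases = np.asarray(unwrapped_phases, dtype=np.float64)
    if phases.shape != data.phase.shape:
        raise ValueError("unwrapped_phases must match the dataset's echoes")
    if phi0 is None:
        phi0 = estimate_phi0_two_echo(phases, te)
    M = data.magnitude
    if weight_scheme == "te_m2":
        w = te[:, None, None, None] * M ** 2
    elif weight_scheme == "magnitude":
        w = M.copy()
    elif weight_scheme == "uniform":
        w = np.ones_like(M)
    else:
        raise ValueError(f"unknown weight scheme: {weight_scheme}")
    wsum = np.sum(w, axis=0)
    per_echo = (phases - phi0[None]) / (2.0 * np.pi * te[:, None, None, None])
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(wsum > 0, np.sum(w * per_echo, axis=0) / wsum, 0.0)
    # noise propagation assuming var(phi_e) = 1 / M_e^2
    with np.errstate(invalid="ignore", divide="ignore"):
        var_pe = np.where(M > 0, 1.0 / (M * 2.0 * np.pi *
                                        te[:, None, None, None]) ** 2, 0.0)
        var_f = np.where(wsum > 0,
                         np.sum(w ** 2 * var_pe, axis=0) / wsum ** 2, np.inf)
    noise = np.sqrt(var_f)
    finite = np.isfinite(noise)
    if finite.any():
        noise = np.where(finite, noise, noise[finite].max())
    quality = _quality_from_noise(noise)
    return TotalFieldResult(field=f, phi0=wrap_phase(phi0), noise=noise,
                            quality=quality, method="weighted")


def nlfit_unwrapped_field(data: MultiEchoDataset, mask,
                          fit: TotalFieldResult | None = None
                          ) -> TotalFieldResult:
    """Nonlinear fit followed by spatial unwrapping of the aliased field.

    The fitted field is rewrapped as ``2 pi f dTE`` into [-pi, pi),
    spatially unwrapped inside the mask with the fit's quality map, and
    rescaled to Hz, removing the temporal aliasing of voxels beyond
    +-1/(2 dTE).
    """
    if fit is None:
        fit = fit_complex_multiecho(data)
    dte = data.meta.delta_te
    psi = wrap_phase(2.0 * np.pi * fit.field * dte)
    psi_u = unwrap_spatial(psi, fit.quality, mask)
    field = np.where(mask, psi_u / (2.0 * np.pi * dte), 0.0)
    return TotalFieldResult(field=field, phi0=fit.phi0, noise=fit.noise,
                            quality=fit.quality, method="nlfit")
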