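"""Diffusion tensor and two-direction estimation plus derived metrics.

Tensor route (full-rank schemes): log-linear least squares (OLS, or WLS
with one reweighting pass using squared predicted signals) on the design
matrix of :func:`scdmri.schemes.design_matrix`, followed by eigenvalue
metrics.  Two-direction route (slice/read schemes): per-direction ADC by
log-linear fit over that direction's b-values plus the b0 volumes, then
the axisymmetric metric formulas.

Fit quality is tracked per voxel in a bit-flag array; questionable
voxels are flagged, never silently altered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dwi_io import DWIStudy
from .schemes import (GradientScheme, design_matrix, is_tensor_estimable,
                      SLICE_AXIS, READ_AXIS)

__all__ = [
    "TensorField", "TensorMetrics", "TwoDirectionEstimate",
    "fit_tensor", "tensor_metrics", "fit_adc_per_direction",
    "two_direction_metrics", "angular_deviation", "frame_projected_metrics",
    "tensor_to_matrix", "RankDeficientSchemeError",
    "FLAG_FLOORED", "FLAG_NEG_EIGENVALUE", "FLAG_FA_CLIPPED",
    "FLAG_DEGENERATE_V1", "FLAG_NEG_INPUT",
]

FLAG_FLOORED = 1          # non-positive signal floored before log
FLAG_NEG_EIGENVALUE = 2   # fitted tensor not positive definite
FLAG_FA_CLIPPED = 4       # raw FA fell outside [0, 1]
FLAG_DEGENERATE_V1 = 8    # λ1 ≈ λ2: principal direction ill-defined
FLAG_NEG_INPUT = 16       # negative ADC input to the two-direction formulas


class RankDeficientSchemeError(ValueError):
    """Scheme cannot support a tensor fit (fewer than 6 independent
    tensor components sampled)."""


@dataclass
class TensorField:
    """Voxelwise tensor fit over a mask.

    ``tensor`` stores the six unique components
    ``(Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)`` in µm²/ms; values are NaN outside
    the mask.
    """

    tensor: np.ndarray   # grid + (6,)
    s0: np.ndarray       # grid
    flags: np.ndarray    # grid, uint8
    mask: np.ndarray     # grid, bool
    method: str


@dataclass
class TensorMetrics:
    """Eigen-decomposition summaries of a tensor field."""

    evals: np.ndarray    # grid + (3,), descending
    v1: np.ndarray       # grid + (3,), unit; NaN where degenerate
    fa: np.ndarray
    md: np.ndarray
    ad: np.ndarray
    rd: np.ndarray
    flags: np.ndarray


@dataclass
class TwoDirectionEstimate:
    """Slice/read-axis metrics from the two-direction protocol."""

    adc_s: np.ndarray
    adc_r: np.ndarray
    ad: np.ndarray       # = adc_s
    rd: np.ndarray       # = adc_r
    md: np.ndarray       # (adc_s + 2 adc_r) / 3
    fa: np.ndarray
    flags: np.ndarray


def tensor_to_matrix(tensor6: np.ndarray) -> np.ndarray:
    """(..., 6) component vector -> (..., 3, 3) symmetric matrix."""
    t = np.asarray(tensor6, dtype=float)
    out = np.empty(t.shape[:-1] + (3, 3))
    xx, yy, zz, xy, xz, yz = (t[..., i] for i in range(6))
    out[..., 0, 0] = xx
    out[..., 1, 1] = yy
    out[..., 2, 2] = zz
    out[..., 0, 1] = out[..., 1, 0] = xy
    out[..., 0, 2] = out[..., 2, 0] = xz
    out[..., 1, 2] = out[..., 2, 1] = yz
    return out


def _floored_log(signals: np.ndarray, flags: np.ndarray) -> np.ndarray:
    """Log of signals with non-positive values floored at eps * S0-scale.

    ``signals`` is (nvox, nvol); flags updated in place.
    """
    s = np.array(signals, dtype=float)
    scale = np.maximum(s.max(axis=1, keepdims=True), 1.0)
    floor = np.finfo(float).eps * scale
    bad = s < floor
    if bad.any():
        flags[bad.any(axis=1)] |= FLAG_FLOORED
        s = np.where(bad, np.broadcast_to(floor, s.shape), s)
    return np.log(s)


def fit_tensor(study: DWIStudy, mask: np.ndarray | None = None,
               method: str = "wls") -> TensorField:
    """Fit the diffusion tensor per voxel.

    ``method='ols'`` solves the log-linear system by least squares;
    ``'wls'`` (default) adds one reweighting pass with weights equal to
    the squared predicted signals.  Both recover noiseless
    mono-exponential data exactly.
    """
    if method not in ("ols", "wls"):
        raise ValueError("method must be 'ols' or 'wls'")
    if not is_tensor_estimable(study.scheme):
        raise RankDeficientSchemeError(
            "scheme design matrix has rank < 7; the tensor is not "
            "estimable — use fit_adc_per_direction / two_direction_metrics "
            "for two-direction protocols"
        )
    grid = study.data.shape[:3]
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    X = design_matrix(study.scheme)            # (nvol, 7)
    S = study.data[mask].astype(float)         # (nvox, nvol)
    vox_flags = np.zeros(S.shape[0], dtype=np.uint8)
    y = _floored_log(S, vox_flags)             # (nvox, nvol)

    beta = np.linalg.lstsq(X, y.T, rcond=None)[0]      # (7, nvox)
    if method == "wls":
        w = np.exp(X @ beta) ** 2                      # (nvol, nvox)
        XtWX = np.einsum("vi,vn,vj->nij", X, w, X)
        XtWy = np.einsum("vi,vn,nv->ni", X, w, y)
        beta = np.linalg.solve(XtWX, XtWy[..., None])[..., 0].T  # (7, nvox)

    tensor = np.full(grid + (6,), np.nan)
    s0 = np.full(grid, np.nan)
    flags = np.zeros(grid, dtype=np.uint8)
    tensor[mask] = beta[:6].T
    s0[mask] = np.exp(beta[6])
    flags[mask] = vox_flags
    return TensorField(tensor=tensor, s0=s0, flags=flags, mask=mask,
                       method=method)


def _fa_from_values(vals: np.ndarray) -> np.ndarray:
    """Standard FA formula on (..., 3) diffusivity triples, unclamped."""
    md = vals.mean(axis=-1)
    num = np.sqrt(((vals - md[..., None]) ** 2).sum(axis=-1))
    den = np.sqrt((vals ** 2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    return np.where(den > 0, fa, 0.0)


def tensor_metrics(field, degenerate_rtol: float = 1e-6) -> TensorMetrics:
    """Eigenvalue metrics of a tensor field.

    Accepts a :class:`TensorField` or a bare (..., 6) component array.
    Eigenvalues are sorted descending; the principal eigenvector sign is
    fixed so its slice-axis component is >= 0.  FA is computed on the
    raw eigenvalues and clipped to [0, 1] afterwards; negative
    eigenvalues and near-degenerate λ1 ≈ λ2 voxels are flagged, with the
    principal direction reported as NaN in the degenerate case.
    """
    if isinstance(field, TensorField):
        tensor6 = field.tensor
        flags = field.flags.astype(np.uint8).copy()
    else:
        tensor6 = np.asarray(field, dtype=float)
        flags = np.zeros(tensor6.shape[:-1], dtype=np.uint8)
    scalar_input = tensor6.ndim == 1
    if scalar_input:
        tensor6 = tensor6[None, :]
        flags = np.atleast_1d(flags)
    D = tensor_to_matrix(tensor6)
    finite = np.isfinite(D).all(axis=(-2, -1))
    Dw = np.where(finite[..., None, None], D, np.eye(3))
    evals, evecs = np.linalg.eigh(Dw)          # ascending
    evals = evals[..., ::-1]
    evecs = evecs[..., :, ::-1]
    v1 = evecs[..., :, 0].copy()
    sign = np.where(v1[..., 2] < 0, -1.0, 1.0)
    v1 *= sign[..., None]

    md = evals.mean(axis=-1)
    ad = evals[..., 0]
    rd = evals[..., 1:].mean(axis=-1)
    fa_raw = _fa_from_values(evals)
    fa = np.clip(fa_raw, 0.0, 1.0)

    neg = evals[..., 2] < 0
    clipped = (fa_raw < 0) | (fa_raw > 1)
    scale = np.maximum(np.abs(evals[..., 0]), np.abs(evals[..., 2]))
    degen = (evals[..., 0] - evals[..., 1]) <= degenerate_rtol * np.maximum(
        scale, np.finfo(float).tiny)
    flags[finite & neg] |= FLAG_NEG_EIGENVALUE
    flags[finite & clipped] |= FLAG_FA_CLIPPED
    flags[finite & degen] |= FLAG_DEGENERATE_V1
    v1[degen] = np.nan

    nanmask = ~finite
    md, ad, rd, fa = (np.where(nanmask, np.nan, arr)
                      for arr in (md, ad, rd, fa))
    evals = np.where(nanmask[..., None], np.nan, evals)
    v1 = np.where(nanmask[..., None], np.nan, v1)
    if scalar_input:
        evals, v1 = evals[0], v1[0]
        fa, md, ad, rd = float(fa[0]), float(md[0]), float(ad[0]), float(rd[0])
        flags = flags[0]
    return TensorMetrics(evals=evals, v1=v1, fa=fa, md=md, ad=ad, rd=rd,
                         flags=flags)


_DIRECTION_AXES = {"slice": SLICE_AXIS, "read": READ_AXIS}


def fit_adc_per_direction(study: DWIStudy, direction: str,
                          mask: np.ndarray | None = None,
                          axis_tol: float = 1e-3) -> np.ndarray:
    """Per-voxel ADC along the slice or read axis (two-direction route).

    Joint log-linear fit of ``ln S`` against b over that direction's
    weighted volumes plus all b0 volumes (slope = -ADC, intercept free);
    exact on noiseless mono-exponential data.
    """
    if direction not in _DIRECTION_AXES:
        raise ValueError("direction must be 'slice' or 'read'")
    axis = _DIRECTION_AXES[direction]
    scheme = study.scheme
    align = np.abs(scheme.directions @ axis)
    sel = np.flatnonzero(align > 1.0 - axis_tol)
    if sel.size == 0:
        raise ValueError(
            f"no weighted volumes along the {direction} axis in this scheme")
    vol_idx = np.concatenate([np.arange(scheme.n_b0), scheme.n_b0 + sel])
    b = np.concatenate([np.zeros(scheme.n_b0), scheme.bvalues[sel]])

    grid = study.data.shape[:3]
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    S = study.data[mask][:, vol_idx].astype(float)
    flags = np.zeros(S.shape[0], dtype=np.uint8)
    y = _floored_log(S, flags)
    X = np.column_stack([-b, np.ones_like(b)])
    beta = np.linalg.lstsq(X, y.T, rcond=None)[0]
    adc = np.full(grid, np.nan)
    adc[mask] = beta[0]
    return adc


def two_direction_metrics(adc_s, adc_r) -> TwoDirectionEstimate:
    """Derived metrics from slice/read apparent diffusivities.

    ``AD = ADC_s``, ``RD = ADC_r``, ``MD = (ADC_s + 2 ADC_r)/3`` and FA
    from the standard formula on the triple (ADC_s, ADC_r, ADC_r).
    The 0/0 case (both diffusivities zero) yields FA = 0; negative
    inputs propagate through the formulas but are flagged.
    """
    adc_s = np.asarray(adc_s, dtype=float)
    adc_r = np.asarray(adc_r, dtype=float)
    if adc_s.shape != adc_r.shape:
        raise ValueError("adc_s and adc_r must have the same shape")
    md = (adc_s + 2.0 * adc_r) / 3.0
    num = np.sqrt((adc_s - md) ** 2 + 2.0 * (adc_r - md) ** 2)
    den = np.sqrt(adc_s ** 2 + 2.0 * adc_r ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0, fa, 0.0)
    flags = np.zeros(adc_s.shape, dtype=np.uint8)
    flags[(adc_s < 0) | (adc_r < 0)] |= FLAG_NEG_INPUT
    return TwoDirectionEstimate(adc_s=adc_s, adc_r=adc_r,
                                ad=adc_s, rd=adc_r, md=md, fa=fa, flags=flags)


def angular_deviation(v1: np.ndarray, slice_axis=SLICE_AXIS) -> np.ndarray:
    """Angle (degrees, in [0, 90]) between the principal eigenvector and
    the slice axis: ``arccos(|v1 · s|)``.  The absolute value reflects
    the sign ambiguity of fiber orientation.  NaN inputs (degenerate
    voxels) propagate to NaN.
    """
    s = np.asarray(slice_axis, dtype=float)
    ns = np.linalg.norm(s)
    if ns == 0:
        raise ValueError("slice axis must be a non-zero vector")
    s = s / ns
    v = np.asarray(v1, dtype=float)
    norm = np.linalg.norm(v, axis=-1)
    if np.any(norm[np.isfinite(norm)] == 0):
        raise ValueError("zero principal eigenvector")
    with np.errstate(invalid="ignore"):
        cosang = np.abs(np.asarray(v) @ s) / norm
    return np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0)))


def frame_projected_metrics(tensor6: np.ndarray, axes: np.ndarray = None,
                            radial: str = "both") -> dict:
    """Metrics from the tensor's diagonal in the imaging frame.

    ``axes`` is a 3x3 orthonormal matrix with rows (read, phase, slice);
    the pseudo-eigenvalues are the diagonal components of the tensor in
    that frame: AD' = slice diagonal, RD' = mean of the two in-plane
    diagonals (``radial='both'``, default) or the read diagonal alone
    (``radial='read'``, protocol-C geometry), MD' = mean of all three
    (hence exactly MD), FA' from the standard formula on the three
    diagonals.  Returns the projected values plus relative deviations
    against the eigenvalue-based metrics.
    """
    if axes is None:
        axes = np.eye(3)
    axes = np.asarray(axes, dtype=float)
    if axes.shape != (3, 3) or not np.allclose(axes @ axes.T, np.eye(3),
                                               atol=1e-10):
        raise ValueError("axes must be a 3x3 orthonormal matrix")
    if radial not in ("both", "read"):
        raise ValueError("radial must be 'both' or 'read'")
    D = tensor_to_matrix(np.asarray(tensor6, dtype=float))
    # diagonal of A D Aᵀ, one entry per frame axis
    diag = np.einsum("ai,...ij,aj->...a", axes, D, axes)
    d_read, d_phase, d_slice = diag[..., 0], diag[..., 1], diag[..., 2]
    ad_p = d_slice
    rd_p = (d_read + d_phase) / 2.0 if radial == "both" else d_read
    md_p = diag.mean(axis=-1)
    fa_p = np.clip(_fa_from_values(diag), 0.0, 1.0)

    ref = tensor_metrics(np.asarray(tensor6, dtype=float))
    with np.errstate(invalid="ignore", divide="ignore"):
        dev = {name: (proj - true) / true
               for name, proj, true in (("AD", ad_p, ref.ad),
                                        ("RD", rd_p, ref.rd),
                                        ("MD", md_p, ref.md),
                                        ("FA", fa_p, ref.fa))}
    return {"AD": ad_p, "RD": rd_p, "MD": md_p, "FA": fa_p,
            "relative_deviation": dev}
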