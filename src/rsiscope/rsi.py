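"""Signal normalization and per-voxel four-compartment fitting (RSIrs maps).

Workflow: scale each patient's diffusion series by the median b=0 signal
inside the prostate, then solve, voxel by voxel, the nonnegative least-squares
problem

    minimise ||A C - S||_2   subject to  C >= 0,

where A is the fixed decay design matrix (see :mod:`rsiscope.model`) and S the
normalized signal across b-values.  The fitted restricted-compartment
coefficient C1 is the RSI restriction score (RSIrs).  Voxels outside the fit
mask carry a quiet NaN sentinel and are excluded from all reductions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .model import DIFFUSION_COEFFS, N_COMPARTMENTS, design_matrix

__all__ = [
    "DwiSeries",
    "CompartmentMaps",
    "RsirsMap",
    "normalize_by_median_b0",
    "build_design_matrix",
    "fit_compartments",
    "compute_rsirs",
    "nnls_many",
]


@dataclass
class DwiSeries:
    """A per-patient stack of direction-averaged volumes, one per b-value.

    ``signal`` is indexed (x, y, z, b) and holds arbitrary scanner units
    before normalization, median-b0-normalized units after.
    """

    signal: np.ndarray
    b_values: tuple[float, ...]
    voxel_size_mm: tuple[float, float, float]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4-D (x, y, z, b)")
        self.b_values = tuple(float(b) for b in self.b_values)
        if self.signal.shape[-1] != len(self.b_values):
            raise ValueError("last signal axis must match the number of b-values")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")

    @property
    def b0_index(self) -> int:
        try:
            return self.b_values.index(0.0)
        except ValueError:
            raise ValueError("series has no b=0 volume") from None


@dataclass
class CompartmentMaps:
    """Fitted per-voxel compartment coefficients C1..C4 plus RMS residual.

    ``c`` is indexed (x, y, z, compartment); out-of-mask voxels are NaN.
    """

    c: np.ndarray
    residual_rms: np.ndarray
    b_values: tuple[float, ...] = ()
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)


@dataclass
class RsirsMap:
    """The RSI restriction score map: the fitted C1 coefficient voxelwise."""

    value: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)


def normalize_by_median_b0(series: DwiSeries, prostate_mask: np.ndarray) -> DwiSeries:
    """Scale all volumes by the median b=0 signal within the prostate mask.

    Idempotent at the fixed point (a series whose masked b=0 median is 1 is
    returned unchanged up to floating point).  Raises on an empty mask or a
    non-positive median, which would make the normalization degenerate.
    """
    mask = np.asarray(prostate_mask, dtype=bool)
    if mask.shape != series.signal.shape[:3]:
        raise ValueError("mask shape does not match the series grid")
    if not mask.any():
        raise ValueError("prostate mask is empty; cannot normalize")
    b0 = series.signal[..., series.b0_index]
    divisor = float(np.median(b0[mask]))
    if divisor <= 0:
        raise ValueError(f"median b=0 signal in mask is {divisor}; must be positive")
    return replace(series, signal=series.signal / divisor, normalized=True)


def build_design_matrix(b_values, diffusion_coeffs=DIFFUSION_COEFFS) -> np.ndarray:
    """Decay design matrix with the flow column as a b=0 indicator."""
    return design_matrix(b_values, diffusion_coeffs)


def _support_solvers(A: np.ndarray):
    """Precompute pseudo-inverses for every nonempty column support of A."""
    p = A.shape[1]
    out = []
    for k in range(1, p + 1):
        for support in itertools.combinations(range(p), k):
            sub = A[:, support]
            out.append((support, sub, np.linalg.pinv(sub)))
    return out


def nnls_many(A: np.ndarray, S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact nonnegative least squares for many right-hand sides at once.

    Enumerates all column supports of ``A`` (feasible because the model has
    only four compartments), solves the unconstrained problem on each support,
    and keeps the feasible candidate with the smallest residual.  The optimal
    NNLS solution restricted to its own support is one of these candidates,
    so the minimum over feasible candidates is the exact NNLS optimum.

    Parameters
    ----------
    A : (n_b, p) design matrix
    S : (n_vox, n_b) right-hand sides

    Returns
    -------
    coeffs : (n_vox, p) nonnegative coefficients
    rss : (n_vox,) residual sums of squares
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    n_vox, n_b = S.shape
    p = A.shape[1]
    best_c = np.zeros((n_vox, p))
    best_rss = np.einsum("ij,ij->i", S, S)  # empty support: C = 0
    feas_tol = 1e-10
    for support, sub, pinv in _support_solvers(A):
        cand = S @ pinv.T
        feasible = (cand >= -feas_tol).all(axis=1)
        if not feasible.any():
            continue
        resid = S - cand @ sub.T
        rss = np.einsum("ij,ij->i", resid, resid)
        # strict improvement keeps the smallest support on ties (deterministic)
        better = feasible & (rss < best_rss - 1e-14)
        if better.any():
            full = np.zeros((int(better.sum()), p))
            full[:, support] = np.clip(cand[better], 0.0, None)
            best_c[better] = full
            best_rss[better] = rss[better]
    return best_c, np.maximum(best_rss, 0.0)


def fit_compartments(
    series: DwiSeries,
    mask: np.ndarray,
    *,
    nonnegative: bool = True,
    diffusion_coeffs=DIFFUSION_COEFFS,
) -> CompartmentMaps:
    """Fit the four-compartment model at every masked voxel.

    The series must already be median-b0 normalized (normalization is part of
    the defined procedure) and provide at least four b-values.  With
    ``nonnegative=False`` an unconstrained least-squares fit is returned for
    comparison; the default enforces C >= 0, since negative compartment signal
    contributions are physically meaningless.
    """
    if not series.normalized:
        raise ValueError("series must be normalized (normalize_by_median_b0) before fitting")
    if len(series.b_values) < N_COMPARTMENTS:
        raise ValueError(
            f"need at least {N_COMPARTMENTS} b-values to fit {N_COMPARTMENTS} compartments"
        )
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.signal.shape[:3]:
        raise ValueError("mask shape does not match the series grid")

    A = design_matrix(series.b_values, diffusion_coeffs)
    S = series.signal[mask]  # (n_vox, n_b)
    if nonnegative:
        coeffs, rss = nnls_many(A, S)
    else:
        coeffs, rss, *_ = np.linalg.lstsq(A, S.T, rcond=None)
        coeffs = coeffs.T
        resid = S - coeffs @ A.T
        rss = np.einsum("ij,ij->i", resid, resid)

    shape = series.signal.shape[:3]
    c = np.full(shape + (N_COMPARTMENTS,), np.nan)
    residual = np.full(shape, np.nan)
    c[mask] = coeffs
    residual[mask] = np.sqrt(rss / len(series.b_values))
    return CompartmentMaps(
        c=c,
        residual_rms=residual,
        b_values=series.b_values,
        voxel_size_mm=series.voxel_size_mm,
    )


def compute_rsirs(maps: CompartmentMaps) -> RsirsMap:
    """The RSI restriction score: the restricted-compartment map C1, voxelwise."""
    return RsirsMap(value=maps.c[..., 0].copy(), voxel_size_mm=maps.voxel_size_mm)
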