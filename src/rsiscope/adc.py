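"""Conventional apparent-diffusion-coefficient (ADC) maps.

ADC is the negative slope of an ordinary least-squares line fit of ln S(b)
against b over a chosen b-value subset, in mm^2/s.  Two maps are used in the
analysis: a vendor-style two-point map from b = 0/1000 (for two points the
slope reduces to ln(S0/S1)/(b1-b0)) and an alternate three-point map from
b = 0/500/1000 computed from the same acquisition.

Voxels with any non-positive signal in the subset (possible under magnitude
noise after background subtraction, and in principle in raw data) are flagged
no-data (NaN) rather than clipped, so that -inf logs can never silently
distort the min-ADC patient reduction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rsi import DwiSeries

__all__ = ["AdcMap", "fit_adc"]


@dataclass
class AdcMap:
    """Voxelwise ADC in mm^2/s; NaN marks out-of-mask or no-data voxels."""

    value: np.ndarray
    b_subset: tuple[float, ...]
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)


def fit_adc(series: DwiSeries, mask: np.ndarray, b_subset=(0.0, 1000.0)) -> AdcMap:
    """Mono-exponential ADC from the chosen b-values at every masked voxel.

    Scale invariant: multiplying all signals by a positive constant shifts
    every ln S(b) by the same amount and leaves the slope unchanged, so the
    map is identical for raw and normalized series.
    """
    subset = tuple(float(b) for b in b_subset)
    if len(subset) < 2 or 0.0 not in subset:
        raise ValueError("b_subset must contain at least two b-values including b=0")
    try:
        idx = [series.b_values.index(b) for b in subset]
    except ValueError as exc:
        raise ValueError(f"b_subset {subset} not present in series b-values {series.b_values}") from exc
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.signal.shape[:3]:
        raise ValueError("mask shape does not match the series grid")
    if not mask.any():
        raise ValueError("mask is empty; cannot fit ADC")

    S = series.signal[mask][:, idx]  # (n_vox, k)
    valid = (S > 0).all(axis=1)
    b = np.array(subset)
    bc = b - b.mean()
    denom = float(bc @ bc)

    adc = np.full(S.shape[0], np.nan)
    if valid.any():
        logS = np.log(S[valid])
        # OLS slope of ln S on b; ADC is its negation
        slope = (logS @ bc) / denom
        adc[valid] = -slope

    out = np.full(series.signal.shape[:3], np.nan)
    out[mask] = adc
    return AdcMap(value=out, b_subset=subset, voxel_size_mm=series.voxel_size_mm)
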