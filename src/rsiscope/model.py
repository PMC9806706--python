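"""Four-compartment diffusion decay model shared by the simulator and the fitter.

The per-voxel direction-averaged signal S(b) is modelled as a nonnegative
linear combination of exponential decays,

    S(b) = C1*exp(-b*D1) + C2*exp(-b*D2) + C3*exp(-b*D3) + C4*f(b),

with fixed, empirically determined diffusion coefficients
D = (1.0e-4, 1.8e-3, 3.6e-3) mm^2/s for the restricted-intracellular,
hindered-extracellular and free-water compartments.  The fourth (vascular
flow) compartment has a coefficient much greater than 3.0e-3 mm^2/s; at the
b-values used here (>= 500 s/mm^2) its decay factor is below 1e-6, so it is
modelled as contributing only at b = 0 (f(0) = 1, f(b>0) = 0).  This keeps
the design matrix well conditioned and is numerically indistinguishable from
any sufficiently large coefficient.

The restricted-compartment coefficient map C1 is the RSI restriction score
(RSIrs), the quantitative cancer biomarker this package evaluates.
"""

from __future__ import annotations

import numpy as np

#: Fixed diffusion coefficients (mm^2/s) of the three decaying compartments:
#: restricted intracellular, hindered extracellular, free water.
DIFFUSION_COEFFS: tuple[float, float, float] = (1.0e-4, 1.8e-3, 3.6e-3)

#: Total number of compartments (three decays + vascular flow).
N_COMPARTMENTS: int = 4


def design_matrix(
    b_values, diffusion_coeffs=DIFFUSION_COEFFS
) -> np.ndarray:
    """Build the (n_b x 4) decay design matrix A with A[j, i] = exp(-b_j * D_i).

    The fourth column is the vascular-flow indicator: 1 where b == 0, else 0.

    Parameters
    ----------
    b_values : array-like of float
        Diffusion weightings in s/mm^2.
    diffusion_coeffs : sequence of 3 floats
        Compartment diffusion coefficients in mm^2/s.
    """
    b = np.asarray(b_values, dtype=float)
    if b.ndim != 1:
        raise ValueError("b_values must be one-dimensional")
    decays = np.exp(-np.outer(b, np.asarray(diffusion_coeffs, dtype=float)))
    flow = (b == 0).astype(float)[:, None]
    return np.hstack([decays, flow])


def forward_signal(fractions, b_values, diffusion_coeffs=DIFFUSION_COEFFS) -> np.ndarray:
    """Noiseless signal vector for compartment fractions (C1..C4).

    `fractions` may be a single 4-vector or an (..., 4) array; the result has
    shape (..., n_b).
    """
    c = np.asarray(fractions, dtype=float)
    if c.shape[-1] != N_COMPARTMENTS:
        raise ValueError(f"fractions must have {N_COMPARTMENTS} components")
    if np.any(c < 0):
        raise ValueError("compartment fractions must be nonnegative")
    A = design_matrix(b_values, diffusion_coeffs)
    return c @ A.T
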