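"""Compiled right-hand side and fixed-step integrator for the quenching model.

The state vector packs the ten chemical concentrations (reduced units) plus
the VDE activity:

    index  0  1  2  3  4   5   6   7   8   9   10
    field  P  V  A  Z  PV  PA  PZ  QV  QA  QZ  alpha

Phase-specific rate coefficients are packed into a 14-vector ``c``:

    0 k_bind_f   1 k_bind_b
    2 fQV  3 fQA  4 fQZ      PX -> QX forward rates (per min)
    5 bQV  6 bQA  7 bQZ      QX -> PX backward rates (per min)
    8 k_VA  9 k_AZ  10 k_ZA  11 k_AV
    12 alpha_max  13 k_VDE

Mass-action conservation of total protein and total labile xanthophyll holds
for the right-hand side by construction.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# State indices
I_P, I_V, I_A, I_Z = 0, 1, 2, 3
I_PV, I_PA, I_PZ = 4, 5, 6
I_QV, I_QA, I_QZ = 7, 8, 9
I_ALPHA = 10
N_STATE = 11


@njit(cache=True)
def rhs(y, c):
    """Time derivative of the packed state under one light phase."""
    dy = np.zeros(N_STATE)
    P = y[I_P]
    V, A, Z = y[I_V], y[I_A], y[I_Z]
    PV, PA, PZ = y[I_PV], y[I_PA], y[I_PZ]
    QV, QA, QZ = y[I_QV], y[I_QA], y[I_QZ]
    alpha = y[I_ALPHA]

    kf, kb = c[0], c[1]
    bind_V = kf * P * V - kb * PV
    bind_A = kf * P * A - kb * PA
    bind_Z = kf * P * Z - kb * PZ

    q_V = c[2] * PV - c[5] * QV
    q_A = c[3] * PA - c[6] * QA
    q_Z = c[4] * PZ - c[7] * QZ

    deep_VA = c[8] * alpha * V
    deep_AZ = c[9] * alpha * A
    epox_ZA = c[10] * Z
    epox_AV = c[11] * A

    dy[I_P] = -(bind_V + bind_A + bind_Z)
    dy[I_V] = -bind_V - deep_VA + epox_AV
    dy[I_A] = -bind_A + deep_VA - deep_AZ + epox_ZA - epox_AV
    dy[I_Z] = -bind_Z + deep_AZ - epox_ZA
    dy[I_PV] = bind_V - q_V
    dy[I_PA] = bind_A - q_A
    dy[I_PZ] = bind_Z - q_Z
    dy[I_QV] = q_V
    dy[I_QA] = q_A
    dy[I_QZ] = q_Z
    dy[I_ALPHA] = c[13] * (c[12] - alpha)
    return dy


@njit(cache=True)
def integrate_segments_rk4(y0, seg_t0, seg_t1, seg_coeff_idx, seg_out_idx,
                           coeffs, dt, out):
    """Classical RK4 over a pre-segmented protocol.

    ``seg_*`` arrays describe consecutive time segments; segment ``i`` runs
    from ``seg_t0[i]`` to ``seg_t1[i]`` under coefficient row
    ``coeffs[seg_coeff_idx[i]]`` and, if ``seg_out_idx[i] >= 0``, its end
    state is stored in ``out[seg_out_idx[i]]``.  Each segment is subdivided
    into equal steps no longer than ``dt``.
    """
    y = y0.copy()
    for i in range(seg_t0.shape[0]):
        span = seg_t1[i] - seg_t0[i]
        c = coeffs[seg_coeff_idx[i]]
        if span > 0.0:
            n = int(np.ceil(span / dt))
            if n < 1:
                n = 1
            h = span / n
            for _ in range(n):
                k1 = rhs(y, c)
                k2 = rhs(y + 0.5 * h * k1, c)
                k3 = rhs(y + 0.5 * h * k2, c)
                k4 = rhs(y + h * k3, c)
                y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        j = seg_out_idx[i]
        if j >= 0:
            out[j] = y
    return y
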