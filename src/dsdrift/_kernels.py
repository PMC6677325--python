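"""Numba-compiled hot paths: patterning score and one-step mutant sweeps.

These duplicate the readable numpy implementation in :mod:`dsdrift.gpmap`
(the reference); the test suite asserts the two agree to machine precision.
Bit vectors are packed in the segment order g_R, g_r, g_M, g_m, g_P, g_B.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["kernel_args", "w_of_bits", "mutant_sweep"]


def kernel_args(params) -> tuple:
    """Scalar argument tuple handed to the jitted kernels."""
    return (
        float(params.eps_pd),
        float(params.eps_pp),
        int(params.ell_pd),
        int(params.ell_pp),
        int(params.n_cells),
        float(params.L),
        float(params.conc_R),
        float(params.conc_M0),
    )


@njit(cache=True)
def _morphogen_cells(alpha, n_cells, L, conc_M0):
    out = np.empty(n_cells)
    s = np.sinh(alpha * L)
    for i in range(n_cells):
        x = (i + 0.5) * L / n_cells
        out[i] = conc_M0 * np.cosh(alpha * (x - L)) / s
    return out


@njit(cache=True)
def _w_from_bits(bits, Mx, eps_pd, eps_pp, ell_pd, ell_pp, L, conc_R):
    # segment offsets in the packed layout
    oR = 0
    o_r = ell_pp
    oM = ell_pp + ell_pd
    o_m = oM + ell_pp
    oP = o_m + ell_pd
    oB = oP + ell_pd

    dRP = 0
    dRB = 0
    dMP = 0
    dMB = 0
    for i in range(ell_pd):
        r = bits[o_r + i]
        m = bits[o_m + i]
        P = bits[oP + i]
        B = bits[oB + i]
        if r != P:
            dRP += 1
        if r != B:
            dRB += 1
        if m != P:
            dMP += 1
        if m != B:
            dMB += 1
    dRM = 0
    dRR = 0
    dMM = 0
    for i in range(ell_pp):
        # contacts are made against the centre-reversed partner face
        if bits[oR + i] != bits[oM + ell_pp - 1 - i]:
            dRM += 1
        if bits[oR + i] != bits[oR + ell_pp - 1 - i]:
            dRR += 1
        if bits[oM + i] != bits[oM + ell_pp - 1 - i]:
            dMM += 1

    # x-independent Boltzmann factors
    aR = conc_R * np.exp(-eps_pd * dRP)          # R on promoter
    bR = conc_R * np.exp(-eps_pd * dRB)          # R on B site
    eMP = np.exp(-eps_pd * dMP)                  # M on promoter, per unit conc
    eMB = np.exp(-eps_pd * dMB)                  # M on B site, per unit conc
    cRM = np.exp(-eps_pp * (ell_pp - dRM))
    cRR = np.exp(-eps_pp * (ell_pp - dRR))
    cMM = np.exp(-eps_pp * (ell_pp - dMM))

    n = Mx.size
    s_ant = 0.0
    s_post = 0.0
    tmax = 0.0
    half = n // 2
    for i in range(n):
        m = Mx[i]
        aM = m * eMP
        bM = m * eMB
        Z = (1.0 + aR + bR + aM + bM
             + aR * bR * cRR + aM * bM * cMM
             + (aR * bM + aM * bR) * cRM)
        T = aR * (1.0 + bR * cRR + bM * cRM) / Z
        if T > tmax:
            tmax = T
        if i < half:
            s_ant += T
        else:
            s_post += T
    if tmax <= 0.0:
        return 0.0
    dx = L / n
    return (s_ant - s_post) * dx / ((L / 2.0) * tmax)


@njit(cache=True)
def w_of_bits(bits, alpha, eps_pd, eps_pp, ell_pd, ell_pp, n_cells, L,
              conc_R, conc_M0):
    """Patterning score W for one packed genome."""
    Mx = _morphogen_cells(alpha, n_cells, L, conc_M0)
    return _w_from_bits(bits, Mx, eps_pd, eps_pp, ell_pd, ell_pp, L, conc_R)


@njit(cache=True)
def mutant_sweep(bits, alpha, alpha_props, eps_pd, eps_pp, ell_pd, ell_pp,
                 n_cells, L, conc_R, conc_M0):
    """W of the current genome and of every one-step mutant.

    Channels 0..n_bits-1 flip one binary site; the remaining channels apply
    the Gaussian alpha perturbations in ``alpha_props``.  A proposal driving
    alpha <= 0 yields NaN (the caller assigns it rate zero).
    """
    n_bits = 4 * ell_pd + 2 * ell_pp
    Mx0 = _morphogen_cells(alpha, n_cells, L, conc_M0)
    w0 = _w_from_bits(bits, Mx0, eps_pd, eps_pp, ell_pd, ell_pp, L, conc_R)
    out = np.empty(n_bits + alpha_props.size)
    for c in range(n_bits):
        bits[c] ^= 1
        out[c] = _w_from_bits(bits, Mx0, eps_pd, eps_pp, ell_pd, ell_pp, L, conc_R)
        bits[c] ^= 1
    for k in range(alpha_props.size):
        na = alpha + alpha_props[k]
        if na <= 0.0:
            out[n_bits + k] = np.nan
        else:
            Mxa = _morphogen_cells(na, n_cells, L, conc_M0)
            out[n_bits + k] = _w_from_bits(bits, Mxa, eps_pd, eps_pp, ell_pd,
                                           ell_pp, L, conc_R)
    return w0, out
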