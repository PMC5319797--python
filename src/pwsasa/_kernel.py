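"""Compiled hot path: cohort dynamics and likelihood evaluation.

These functions are written against flat float64 arrays so numba can compile
them; the readable public API lives in :mod:`pwsasa.population` and
:mod:`pwsasa.objective`, which wrap and document them.  Parameter layout
follows :class:`pwsasa.params.ParamLayout` (17 scalars, then one log
recruitment per year, then log 1980 abundance at ages 4 and 5).

Status codes: 0 feasible, 1 negative intermediate abundance (catch exceeds
fish available), 2 degenerate denominator, 3 non-positive prediction on a
fitted year.  Any non-zero status maps to -inf log posterior upstream.
"""

import math

import numpy as np
from numba import njit

N_SCALARS = 17  # keep in sync with pwsasa.params

# calendar breakpoints (fixed by the model structure, not estimated)
_LAST_PRE_DISEASE = 1991   # background mortality through this year
_YEAR_1993 = 1993          # estimated extra-disease-M year (also 1992 H2)
_DISEASE_INDEX_START = 1994
_ERA2_START = 2007         # second I. hoferi scalar era
_REGIME2_START = 1997      # second maturity regime


@njit(cache=True)
def run_model(theta, ny, na, year0, w, rho_f, C2, C3, C4, seine_yield,
              d1, d2, m_base, rho_k, rhoM24):
    """Catch-conditioned cohort projection plus derived biomasses.

    Returns (status, N, Ntilde, B, Btilde, Btilde_post, Sf, Ss, Chat1,
    ChatS, Theta1hat, maturity).  ``N`` has ``ny + 1`` rows: the final row
    is the one-year-ahead projection of ages 4+ (age-3 entry left zero).
    """
    mu9plus = theta[0]
    beta1 = theta[1]
    beta2_1 = theta[2]
    beta2_2 = theta[3]
    mu1_1993 = theta[4]
    mu2_1993 = theta[5]
    alpha_v = theta[6]
    beta_v = theta[7]
    nu3 = theta[14]
    rhoM_1_4 = theta[15]
    rhoM_2_3 = theta[16]

    status = 0
    N = np.zeros((ny + 1, na))
    Ntilde = np.zeros((ny, na))
    B = np.zeros(ny)
    Btilde = np.zeros(ny)
    Btpost = np.zeros(ny)
    Sf = np.zeros((ny, na))
    Ss = np.zeros((ny, na))
    Chat1 = np.zeros(ny)
    ChatS = np.zeros((ny, na))
    Th1 = np.zeros((ny, na))
    mat = np.zeros((ny, na))

    # --- half-year survival schedules -----------------------------------
    for iy in range(ny):
        yr = year0 + iy
        for ia in range(na - 1):
            if yr <= _LAST_PRE_DISEASE:
                mf = m_base
                ms = m_base
            elif yr == _LAST_PRE_DISEASE + 1:      # 1992: H1 background, H2 as 1993
                mf = m_base
                ms = m_base + (mu1_1993 if ia < 2 else mu2_1993)
            elif yr == _YEAR_1993:
                mf = m_base + (mu1_1993 if ia < 2 else mu2_1993)
                ms = mf
            else:
                if ia < 2:
                    mf = m_base + beta1 * d1[iy]
                else:
                    b2 = beta2_1 if yr < _ERA2_START else beta2_2
                    mf = m_base + b2 * d2[iy]
                ms = mf
            Sf[iy, ia] = math.exp(-0.5 * mf)
            Ss[iy, ia] = math.exp(-0.5 * ms)
        # plus group: fixed total M through 1991, then tracks the age-8 ratio
        if yr <= _LAST_PRE_DISEASE:
            Sf[iy, na - 1] = math.exp(-0.5 * mu9plus)
            Ss[iy, na - 1] = math.exp(-0.5 * mu9plus)
        else:
            Sf[iy, na - 1] = Sf[iy - 1, na - 1] * Sf[iy, na - 2] / Sf[iy - 1, na - 2]
            Ss[iy, na - 1] = Ss[iy - 1, na - 1] * Ss[iy, na - 2] / Ss[iy - 1, na - 2]
        for ia in range(na):
            if Sf[iy, ia] <= 0.0 or Sf[iy, ia] > 1.0 or Ss[iy, ia] <= 0.0 or Ss[iy, ia] > 1.0:
                status = 2

    # --- maturity schedule ----------------------------------------------
    for iy in range(ny):
        yr = year0 + iy
        if yr < _REGIME2_START:
            mat[iy, 0] = nu3 * rhoM_1_4
            if na > 1:
                mat[iy, 1] = rhoM_1_4
        else:
            mat[iy, 0] = rhoM_2_3
            if na > 1:
                mat[iy, 1] = rhoM24
        for ia in range(2, na):
            mat[iy, ia] = 1.0

    # --- initial abundance ----------------------------------------------
    eta0 = theta[N_SCALARS]
    N[0, 0] = math.exp(eta0)
    if na > 1:
        N[0, 1] = math.exp(theta[N_SCALARS + ny])
    if na > 2:
        N[0, 2] = math.exp(theta[N_SCALARS + ny + 1])

    # --- annual cycle: seine comp -> removals -> survival x2 -------------
    for iy in range(ny):
        if iy > 0:
            N[iy, 0] = math.exp(theta[N_SCALARS + iy])
        vn = 0.0
        for ia in range(na):
            age = 3.0 + ia
            v = 1.0 / (1.0 + math.exp(-beta_v * (age - alpha_v)))
            Th1[iy, ia] = v * N[iy, ia]
            vn += Th1[iy, ia]
        if vn <= 0.0:
            status = 2
            break
        sw = 0.0
        for ia in range(na):
            Th1[iy, ia] /= vn
            sw += Th1[iy, ia] * w[iy, ia]
        if seine_yield[iy] > 0.0:
            if sw <= 0.0:
                status = 2
                break
            Chat1[iy] = seine_yield[iy] / sw
        bsum = 0.0
        bmat = 0.0
        bpost = 0.0
        for ia in range(na):
            seine_a = Th1[iy, ia] * Chat1[iy]
            ChatS[iy, ia] = seine_a + C2[iy, ia] + rho_k * C3[iy, ia]
            after_a = N[iy, ia] - ChatS[iy, ia]
            if after_a < 0.0:
                status = 1
            after_b = after_a * Sf[iy, ia] - C4[iy, ia]
            if after_b < 0.0:
                status = 1
            surv = after_b * Ss[iy, ia]
            if ia < na - 2:
                N[iy + 1, ia + 1] = surv
            else:
                N[iy + 1, na - 1] += surv
            spawn_base = N[iy, ia] - (seine_a + C2[iy, ia] + C3[iy, ia])
            if spawn_base < 0.0:
                status = 1
            Ntilde[iy, ia] = mat[iy, ia] * spawn_base
            bsum += N[iy, ia] * w[iy, ia]
            bmat += mat[iy, ia] * N[iy, ia] * w[iy, ia]
            bpost += Ntilde[iy, ia] * w[iy, ia]
        if status != 0:
            break
        B[iy] = bsum
        Btilde[iy] = bmat
        Btpost[iy] = bpost

    return status, N, Ntilde, B, Btilde, Btpost, Sf, Ss, Chat1, ChatS, Th1, mat


@njit(cache=True)
def neg_log_like(theta, ny, na, year0, w, rho_f, C2, C3, C4, seine_yield,
                 d1, d2, m_base, rho_k, rhoM24, sigma_egg_extra, fec,
                 seine_comp, seine_comp_mask, spawn_comp, spawn_comp_mask,
                 eggs, egg_cv, egg_mask, h1, h1_mask, h2, h2_cv, h2_mask,
                 milt, milt_mask, z1, zsp):
    """Six negative log-likelihood components given data and effective sample sizes.

    Returns (status, L) with L a length-6 array: seine comps, spawner comps,
    egg deposition, ADF&G acoustic, PWSSC acoustic, milt.
    """
    out = np.zeros(6)
    res = run_model(theta, ny, na, year0, w, rho_f, C2, C3, C4, seine_yield,
                    d1, d2, m_base, rho_k, rhoM24)
    status = res[0]
    if status != 0:
        return status, out
    N = res[1]
    Ntilde = res[2]
    B = res[3]
    Btpost = res[5]
    Th1 = res[10]
    mat = res[11]

    q1 = theta[8]
    sigma_h1 = theta[9]
    q2 = theta[10]
    sigma_h2b = theta[11]
    qT = theta[12]
    sigma_t = theta[13]
    eps = 1e-8

    for iy in range(ny):
        # multinomial (KL-form) composition components
        if seine_comp_mask[iy]:
            s = 0.0
            for ia in range(na):
                th = seine_comp[iy, ia]
                if th > 0.0:
                    phat = Th1[iy, ia]
                    if phat < eps:
                        phat = eps
                    s += th * math.log(phat / th)
            out[0] -= z1[iy] * s
        if spawn_comp_mask[iy]:
            denom = 0.0
            for ia in range(na):
                denom += mat[iy, ia] * N[iy, ia]
            if denom <= 0.0:
                return 2, out
            s = 0.0
            for ia in range(na):
                th = spawn_comp[iy, ia]
                if th > 0.0:
                    phat = mat[iy, ia] * N[iy, ia] / denom
                    if phat < eps:
                        phat = eps
                    s += th * math.log(phat / th)
            out[1] -= zsp[iy] * s
        # lognormal index components
        if egg_mask[iy]:
            ehat = 0.0
            for ia in range(na):
                ehat += Ntilde[iy, ia] * fec[iy, ia]
            ehat *= 1e-6 * rho_f[iy]
            if ehat <= 0.0 or eggs[iy] <= 0.0:
                return 3, out
            sig = math.sqrt(egg_cv[iy] ** 2 + sigma_egg_extra ** 2)
            r = math.log(ehat) - math.log(eggs[iy])
            out[2] += math.log(sig) + r * r / (2.0 * sig * sig)
        if h1_mask[iy]:
            pred = B[iy] * math.exp(q1)
            if pred <= 0.0 or h1[iy] <= 0.0:
                return 3, out
            r = math.log(pred) - math.log(h1[iy])
            out[3] += math.log(sigma_h1) + r * r / (2.0 * sigma_h1 * sigma_h1)
        if h2_mask[iy]:
            pred = B[iy] * math.exp(q2)
            if pred <= 0.0 or h2[iy] <= 0.0:
                return 3, out
            sig = math.sqrt(h2_cv[iy] ** 2 + sigma_h2b ** 2)
            r = math.log(pred) - math.log(h2[iy])
            out[4] += math.log(sig) + r * r / (2.0 * sig * sig)
        if milt_mask[iy]:
            pred = (1.0 - rho_f[iy]) * Btpost[iy] / math.exp(qT)
            if pred <= 0.0 or milt[iy] <= 0.0:
                return 3, out
            r = math.log(pred) - math.log(milt[iy])
            out[5] += math.log(sigma_t) + r * r / (2.0 * sigma_t * sigma_t)
    return 0, out
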