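"""Numba kernels for the single-site Gibbs samplers.

All samplers update location effects one at a time with residual updating
(the memory-light scheme of the GIBBS1F90 family): the residual vector
e = y - X beta - Z alpha is kept current, so each scalar conditional needs
only the records carrying that effect plus, for breeding values, one sparse
row of A-inverse.  Variance components are drawn from their scaled
inverse-chi-square (single trait) or inverse-Wishart (two traits) full
conditionals.

Truncated-normal draws use the inverse-CDF method with complementary-tail
evaluation so that extreme intervals (|eta| large) stay accurate.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

SQRT2 = math.sqrt(2.0)
LOG2PI = math.log(2.0 * math.pi)
TINY = 1e-300


# ---------------------------------------------------------------------------
# normal CDF / quantile


@njit(cache=True)
def _norm_cdf(x):
    return 0.5 * math.erfc(-x / SQRT2)


@njit(cache=True)
def _norm_sf(x):
    return 0.5 * math.erfc(x / SQRT2)


@njit(cache=True)
def _ndtri(p):
    """Inverse standard-normal CDF (Acklam's rational approximation plus one
    Halley refinement; ~1e-15 relative accuracy over (0, 1))."""
    if p <= 0.0:
        return -np.inf
    if p >= 1.0:
        return np.inf
    # coefficients
    a0, a1, a2 = -3.969683028665376e01, 2.209460984245205e02, -2.759285104469687e02
    a3, a4, a5 = 1.383577518672690e02, -3.066479806614716e01, 2.506628277459239e00
    b0, b1, b2 = -5.447609879822406e01, 1.615858368580409e02, -1.556989798598866e02
    b3, b4 = 6.680131188771972e01, -1.328068155288572e01
    c0, c1, c2 = -7.784894002430293e-03, -3.223964580411365e-01, -2.400758277161838e00
    c3, c4, c5 = -2.549732539343734e00, 4.374664141464968e00, 2.938163982698783e00
    d0, d1, d2, d3 = 7.784695709041462e-03, 3.224671290700398e-01, 2.445134137142996e00, 3.754408661907416e00
    plow = 0.02425
    if p < plow:
        q = math.sqrt(-2.0 * math.log(p))
        x = (((((c0 * q + c1) * q + c2) * q + c3) * q + c4) * q + c5) / (
            (((d0 * q + d1) * q + d2) * q + d3) * q + 1.0
        )
    elif p <= 1.0 - plow:
        q = p - 0.5
        r = q * q
        x = (((((a0 * r + a1) * r + a2) * r + a3) * r + a4) * r + a5) * q / (
            ((((b0 * r + b1) * r + b2) * r + b3) * r + b4) * r + 1.0
        )
    else:
        q = math.sqrt(-2.0 * math.log(1.0 - p))
        x = -(((((c0 * q + c1) * q + c2) * q + c3) * q + c4) * q + c5) / (
            (((d0 * q + d1) * q + d2) * q + d3) * q + 1.0
        )
    # Halley refinement
    err = _norm_cdf(x) - p
    u = err * math.sqrt(2.0 * math.pi) * math.exp(0.5 * x * x)
    x = x - u / (1.0 + 0.5 * x * u)
    return x


@njit(cache=True)
def _truncnorm(mu, sd, lo, hi):
    """Draw from N(mu, sd^2) truncated to (lo, hi] by inverse CDF.

    Works in whichever tail representation keeps the interval probabilities
    away from cancellation.
    """
    a = (lo - mu) / sd
    b = (hi - mu) / sd
    if a >= 0.0:
        # right tail: work with survival probabilities
        qa = _norm_sf(a)
        qb = _norm_sf(b)
        u = qb + np.random.random() * (qa - qb)
        if u <= 0.0:
            u = TINY
        z = -_ndtri(u)
    elif b <= 0.0:
        pa = _norm_cdf(a)
        pb = _norm_cdf(b)
        u = pa + np.random.random() * (pb - pa)
        if u <= 0.0:
            u = TINY
        z = _ndtri(u)
    else:
        pa = _norm_cdf(a)
        pb = _norm_cdf(b)
        u = pa + np.random.random() * (pb - pa)
        z = _ndtri(u)
    if z <= a:
        z = a + 1e-10
    if z > b:
        z = b - 1e-10 if np.isfinite(b) else b
    return mu + sd * z


@njit(cache=True)
def _log_cat_prob(eta, lo, hi):
    """log( Phi(hi - eta) - Phi(lo - eta) ), computed in the stabler tail."""
    a = lo - eta
    b = hi - eta
    if a >= 0.0:
        p = _norm_sf(a) - _norm_sf(b)
    elif b <= 0.0:
        p = _norm_cdf(b) - _norm_cdf(a)
    else:
        p = _norm_cdf(b) - _norm_cdf(a)
    if p < TINY:
        p = TINY
    return math.log(p)


# ---------------------------------------------------------------------------
# shared location-effect sweeps


@njit(cache=True)
def _update_fixed(beta, e, col_indptr, col_recs, xtx, se2):
    p = beta.shape[0]
    for k in range(p):
        nk = xtx[k]
        if nk <= 0.0:
            continue
        s = 0.0
        for ii in range(col_indptr[k], col_indptr[k + 1]):
            s += e[col_recs[ii]]
        # increment parameterization: c = beta_new - beta_old
        c = s / nk + np.random.standard_normal() * math.sqrt(se2 / nk)
        beta[k] += c
        for ii in range(col_indptr[k], col_indptr[k + 1]):
            e[col_recs[ii]] -= c


@njit(cache=True)
def _update_animals(alpha, e, anim_indptr, anim_recs, ai_indptr, ai_indices, ai_data, lam, se2):
    n_anim = alpha.shape[0]
    for i in range(n_anim):
        nrec = float(anim_indptr[i + 1] - anim_indptr[i])
        s = 0.0
        for ii in range(anim_indptr[i], anim_indptr[i + 1]):
            s += e[anim_recs[ii]]
        aii = 0.0
        u = 0.0  # full row product (A^-1 alpha)_i
        for jj in range(ai_indptr[i], ai_indptr[i + 1]):
            j = ai_indices[jj]
            v = ai_data[jj]
            u += v * alpha[j]
            if j == i:
                aii = v
        denom = nrec + lam * aii
        # increment form: rhs for c = alpha_new - alpha_old
        b = s - lam * u
        c = b / denom + np.random.standard_normal() * math.sqrt(se2 / denom)
        alpha[i] += c
        for ii in range(anim_indptr[i], anim_indptr[i + 1]):
            e[anim_recs[ii]] -= c


@njit(cache=True)
def _quad_ainv(alpha, ai_indptr, ai_indices, ai_data):
    n = alpha.shape[0]
    tot = 0.0
    for i in range(n):
        ui = 0.0
        for jj in range(ai_indptr[i], ai_indptr[i + 1]):
            ui += ai_data[jj] * alpha[ai_indices[jj]]
        tot += alpha[i] * ui
    return tot


# ---------------------------------------------------------------------------
# single-trait linear sampler


@njit(cache=True)
def linear_kernel(
    y,
    col_indptr,
    col_recs,
    xtx,
    anim_indptr,
    anim_recs,
    ai_indptr,
    ai_indices,
    ai_data,
    n_cycles,
    burn_in,
    thin,
    seed,
    nu_a,
    nu_e,
    sa2_0,
    se2_0,
):
    np.random.seed(seed)
    n = y.shape[0]
    p = xtx.shape[0]
    n_anim = ai_indptr.shape[0] - 1
    m = (n_cycles - burn_in) // thin

    beta = np.zeros(p)
    alpha = np.zeros(n_anim)
    e = y.copy()
    sa2 = sa2_0
    se2 = se2_0

    out = np.empty((m, 3))  # sa2, se2, loglik
    beta_sum = np.zeros(p)
    alpha_sum = np.zeros(n_anim)
    kept = 0
    err_cycle = -1

    for cyc in range(n_cycles):
        _update_fixed(beta, e, col_indptr, col_recs, xtx, se2)
        lam = se2 / sa2
        _update_animals(alpha, e, anim_indptr, anim_recs, ai_indptr, ai_indices, ai_data, lam, se2)

        qa = _quad_ainv(alpha, ai_indptr, ai_indices, ai_data)
        sa2 = qa / np.random.chisquare(n_anim + nu_a)
        if sa2 < 1e-12:
            sa2 = 1e-12
        ss = 0.0
        for r in range(n):
            ss += e[r] * e[r]
        se2 = ss / np.random.chisquare(n + nu_e)
        if not (np.isfinite(sa2) and np.isfinite(se2)) or se2 <= 0.0:
            err_cycle = cyc
            break

        if cyc >= burn_in and (cyc - burn_in) % thin == thin - 1:
            ll = -0.5 * (n * (LOG2PI + math.log(se2)) + ss / se2)
            out[kept, 0] = sa2
            out[kept, 1] = se2
            out[kept, 2] = ll
            beta_sum += beta
            alpha_sum += alpha
            kept += 1

    return out, beta_sum, alpha_sum, kept, err_cycle


# ---------------------------------------------------------------------------
# single-trait threshold sampler


@njit(cache=True)
def threshold_kernel(
    ycat,
    col_indptr,
    col_recs,
    xtx,
    anim_indptr,
    anim_recs,
    ai_indptr,
    ai_indices,
    ai_data,
    K,
    t_init,
    n_cycles,
    burn_in,
    thin,
    seed,
    nu_a,
    nu_e,
    sa2_0,
    se2_0,
    sample_thresholds,
):
    """Liability-model Gibbs sampler.

    Identification: with ``sample_thresholds`` false (default) all thresholds
    are held fixed at ``t_init`` (t_1 = 0) and the residual variance is
    estimated — the THRGIBBS1F90-style scheme; this pins the liability scale
    through the threshold spacing and keeps flat priors proper.  With
    ``sample_thresholds`` true the Albert–Chib scheme is used instead:
    sigma_e^2 = 1 and interior thresholds t_2..t_{K-1} get uniform conditional
    draws (prone to a separation-driven scale drift when the fixed-effect
    structure can nearly classify the categories; see the package docs).
    For K = 2 the residual variance is always fixed at 1.
    """
    np.random.seed(seed)
    n = ycat.shape[0]
    p = xtx.shape[0]
    n_anim = ai_indptr.shape[0] - 1
    m = (n_cycles - burn_in) // thin

    # thresholds: t[0] = -inf, t[1..K-1] interior (t[1] = 0), t[K] = +inf
    t = np.empty(K + 1)
    t[0] = -np.inf
    t[K] = np.inf
    for j in range(1, K):
        t[j] = t_init[j - 1]

    estimate_se2 = (K > 2) and (not sample_thresholds)
    beta = np.zeros(p)
    alpha = np.zeros(n_anim)
    sa2 = sa2_0
    se2 = se2_0 if estimate_se2 else 1.0
    # init liabilities at interval midpoints (open ends pulled in by 0.5)
    U = np.empty(n)
    for r in range(n):
        j = ycat[r]
        lo = t[j - 1] if j > 1 else t[1] - 1.0
        hi = t[j] if j < K else t[K - 1] + 1.0
        U[r] = 0.5 * (lo + hi)
    e = U.copy()  # eta starts at 0

    out = np.empty((m, 4))  # sa2, se2, h2, loglik
    out_t = np.empty((m, K - 2)) if K > 2 else np.empty((m, 0))
    beta_sum = np.zeros(p)
    alpha_sum = np.zeros(n_anim)
    t_sum = np.zeros(K + 1)
    kept = 0
    err_cycle = -1

    maxu = np.empty(K + 1)
    minu = np.empty(K + 1)

    for cyc in range(n_cycles):
        # 1. liabilities
        sd = math.sqrt(se2)
        for r in range(n):
            j = ycat[r]
            eta = U[r] - e[r]
            un = _truncnorm(eta, sd, t[j - 1], t[j])
            U[r] = un
            e[r] = un - eta

        # 2. location effects
        _update_fixed(beta, e, col_indptr, col_recs, xtx, se2)
        lam = se2 / sa2
        _update_animals(alpha, e, anim_indptr, anim_recs, ai_indptr, ai_indices, ai_data, lam, se2)

        # 3. variance components
        qa = _quad_ainv(alpha, ai_indptr, ai_indices, ai_data)
        sa2 = qa / np.random.chisquare(n_anim + nu_a)
        if sa2 < 1e-12:
            sa2 = 1e-12
        if estimate_se2:
            ss = 0.0
            for r in range(n):
                ss += e[r] * e[r]
            se2 = ss / np.random.chisquare(n + nu_e)
        if not (np.isfinite(sa2) and np.isfinite(se2)) or se2 <= 0.0:
            err_cycle = cyc
            break

        # 4. optional Albert-Chib threshold draws:
        #    t[2..K-1] ~ U(max U in cat j, min U in cat j+1)
        if sample_thresholds and K > 2:
            for j in range(1, K + 1):
                maxu[j] = -np.inf
                minu[j] = np.inf
            for r in range(n):
                j = ycat[r]
                if U[r] > maxu[j]:
                    maxu[j] = U[r]
                if U[r] < minu[j]:
                    minu[j] = U[r]
            for j in range(2, K):
                lo = maxu[j]
                hi = minu[j + 1]
                t[j] = lo + np.random.random() * (hi - lo)

        if cyc >= burn_in and (cyc - burn_in) % thin == thin - 1:
            sd = math.sqrt(se2)
            ll = 0.0
            for r in range(n):
                j = ycat[r]
                eta = U[r] - e[r]
                ll += _log_cat_prob(eta / sd, t[j - 1] / sd, t[j] / sd)
            out[kept, 0] = sa2
            out[kept, 1] = se2
            out[kept, 2] = sa2 / (sa2 + se2)
            out[kept, 3] = ll
            for j in range(2, K):
                out_t[kept, j - 2] = t[j]
            beta_sum += beta
            alpha_sum += alpha
            t_sum += np.where(np.isfinite(t), t, 0.0)
            kept += 1

    return out, out_t, beta_sum, alpha_sum, t_sum, kept, err_cycle


# ---------------------------------------------------------------------------
# 2x2 helpers for the bivariate sampler


@njit(cache=True)
def _inv2(m11, m12, m22):
    det = m11 * m22 - m12 * m12
    return m22 / det, -m12 / det, m11 / det


@njit(cache=True)
def _draw_iw2(s11, s12, s22, df):
    """Draw a 2x2 inverse-Wishart(df, S) via Bartlett on the Wishart of S^-1."""
    v11, v12, v22 = _inv2(s11, s12, s22)
    # chol of V = S^-1 (lower)
    l11 = math.sqrt(v11)
    l21 = v12 / l11
    l22 = math.sqrt(v22 - l21 * l21)
    # Bartlett factor
    a11 = math.sqrt(np.random.chisquare(df))
    a21 = np.random.standard_normal()
    a22 = math.sqrt(np.random.chisquare(df - 1.0))
    # T = L @ A (lower), W = T T'
    t11 = l11 * a11
    t21 = l21 * a11 + l22 * a21
    t22 = l22 * a22
    w11 = t11 * t11
    w12 = t11 * t21
    w22 = t21 * t21 + t22 * t22
    return _inv2(w11, w12, w22)


@njit(cache=True)
def bivariate_kernel(
    ycont,
    ycat,
    col_indptr,
    col_recs,
    xtx,
    anim_indptr,
    anim_recs,
    ai_indptr,
    ai_indices,
    ai_data,
    K,
    t_init,
    n_cycles,
    burn_in,
    thin,
    seed,
    nu0,
    g11_0,
    g22_0,
    r11_0,
    r22_0,
):
    """Two-trait sampler: trait 0 categorical (liability), trait 1 continuous.

    Both traits share the fixed-effect design.  Identification follows the
    fixed-threshold scheme (K >= 3): all thresholds are held at ``t_init``
    (t_1 = 0), which pins the liability scale, so the full 2x2 residual
    covariance R0 is estimable and is drawn from its inverse-Wishart
    conditional.  G0 and R0 both get flat (improper-limit) inverse-Wishart
    priors: df ``nu0`` = -(k+1) with a tiny identity scale that keeps the
    Bartlett draw defined when a cross-product matrix is near singular.
    """
    np.random.seed(seed)
    n = ycat.shape[0]
    p = xtx.shape[0]
    n_anim = ai_indptr.shape[0] - 1
    m = (n_cycles - burn_in) // thin

    t = np.empty(K + 1)
    t[0] = -np.inf
    t[K] = np.inf
    for j in range(1, K):
        t[j] = t_init[j - 1]

    beta1 = np.zeros(p)  # categorical (liability scale)
    beta2 = np.zeros(p)  # continuous
    a1 = np.zeros(n_anim)
    a2 = np.zeros(n_anim)
    g11, g12, g22 = g11_0, 0.0, g22_0
    r11, r12, r22 = r11_0, 0.0, r22_0

    U = np.empty(n)
    for r in range(n):
        j = ycat[r]
        lo = t[j - 1] if j > 1 else t[1] - 1.0
        hi = t[j] if j < K else t[K - 1] + 1.0
        U[r] = 0.5 * (lo + hi)
    e1 = U.copy()
    e2 = ycont.copy()

    # retained: g11 g12 g22 r11 r12 r22 rg h2cat h2cont
    out = np.empty((m, 9))
    kept = 0
    err_cycle = -1
    jitter_count = 0

    for cyc in range(n_cycles):
        ri11, ri12, ri22 = _inv2(r11, r12, r22)
        gi11, gi12, gi22 = _inv2(g11, g12, g22)

        # 1. liabilities given the continuous residual
        cmu_slope = r12 / r22
        cvar = r11 - r12 * r12 / r22
        csd = math.sqrt(cvar)
        for r in range(n):
            j = ycat[r]
            eta = U[r] - e1[r]
            mu = eta + cmu_slope * e2[r]
            un = _truncnorm(mu, csd, t[j - 1], t[j])
            U[r] = un
            e1[r] = un - eta

        # 2. fixed effects, per trait, scalar increments
        for k in range(p):
            nk = xtx[k]
            if nk <= 0.0:
                continue
            s1 = 0.0
            s2 = 0.0
            for ii in range(col_indptr[k], col_indptr[k + 1]):
                r = col_recs[ii]
                s1 += ri11 * e1[r] + ri12 * e2[r]
                s2 += ri12 * e1[r] + ri22 * e2[r]
            # trait 0
            c = s1 / (nk * ri11) + np.random.standard_normal() / math.sqrt(nk * ri11)
            beta1[k] += c
            for ii in range(col_indptr[k], col_indptr[k + 1]):
                e1[col_recs[ii]] -= c
            # trait 1 (recompute cross term with updated e1)
            s2 = 0.0
            for ii in range(col_indptr[k], col_indptr[k + 1]):
                r = col_recs[ii]
                s2 += ri12 * e1[r] + ri22 * e2[r]
            c = s2 / (nk * ri22) + np.random.standard_normal() / math.sqrt(nk * ri22)
            beta2[k] += c
            for ii in range(col_indptr[k], col_indptr[k + 1]):
                e2[col_recs[ii]] -= c

        # 3. breeding values, joint 2-vector per animal
        for i in range(n_anim):
            nrec = float(anim_indptr[i + 1] - anim_indptr[i])
            s1 = 0.0
            s2 = 0.0
            for ii in range(anim_indptr[i], anim_indptr[i + 1]):
                r = anim_recs[ii]
                s1 += e1[r]
                s2 += e2[r]
            aii = 0.0
            u1 = 0.0
            u2 = 0.0
            for jj in range(ai_indptr[i], ai_indptr[i + 1]):
                jx = ai_indices[jj]
                v = ai_data[jj]
                u1 += v * a1[jx]
                u2 += v * a2[jx]
                if jx == i:
                    aii = v
            # posterior precision P and linear term b for the increment c
            p11 = nrec * ri11 + aii * gi11
            p12 = nrec * ri12 + aii * gi12
            p22 = nrec * ri22 + aii * gi22
            b1 = ri11 * s1 + ri12 * s2 - (gi11 * u1 + gi12 * u2)
            b2 = ri12 * s1 + ri22 * s2 - (gi12 * u1 + gi22 * u2)
            # chol of P
            l11 = math.sqrt(p11)
            l21 = p12 / l11
            l22v = p22 - l21 * l21
            if l22v <= 0.0:
                l22v = 1e-12
            l22 = math.sqrt(l22v)
            # mean = P^-1 b via forward/back solve
            w1 = b1 / l11
            w2 = (b2 - l21 * w1) / l22
            z2 = (w2 + np.random.standard_normal()) / l22
            z1 = (w1 + np.random.standard_normal() - l21 * z2) / l11
            a1[i] += z1
            a2[i] += z2
            for ii in range(anim_indptr[i], anim_indptr[i + 1]):
                r = anim_recs[ii]
                e1[r] -= z1
                e2[r] -= z2

        # 4. genetic covariance matrix: S_a = alpha' A^-1 alpha (2x2)
        s11 = 0.0
        s12 = 0.0
        s22 = 0.0
        for i in range(n_anim):
            u1 = 0.0
            u2 = 0.0
            for jj in range(ai_indptr[i], ai_indptr[i + 1]):
                jx = ai_indices[jj]
                v = ai_data[jj]
                u1 += v * a1[jx]
                u2 += v * a2[jx]
            s11 += a1[i] * u1
            s12 += a1[i] * u2
            s22 += a2[i] * u2
        g11, g12, g22 = _draw_iw2(s11 + 1e-6, s12, s22 + 1e-6, float(n_anim) + nu0)
        det = g11 * g22 - g12 * g12
        if det <= 0.0 or not np.isfinite(det):
            g12 = 0.0
            jitter_count += 1

        # 5. residual covariance: inverse-Wishart on residual cross-products
        s11 = 0.0
        s12 = 0.0
        s22 = 0.0
        for r in range(n):
            s11 += e1[r] * e1[r]
            s12 += e1[r] * e2[r]
            s22 += e2[r] * e2[r]
        r11, r12, r22 = _draw_iw2(s11 + 1e-6, s12, s22 + 1e-6, float(n) + nu0)

        if not (np.isfinite(g11) and np.isfinite(g22) and np.isfinite(r11) and np.isfinite(r22)):
            err_cycle = cyc
            break

        if cyc >= burn_in and (cyc - burn_in) % thin == thin - 1:
            out[kept, 0] = g11
            out[kept, 1] = g12
            out[kept, 2] = g22
            out[kept, 3] = r11
            out[kept, 4] = r12
            out[kept, 5] = r22
            out[kept, 6] = g12 / math.sqrt(g11 * g22)
            out[kept, 7] = g11 / (g11 + r11)
            out[kept, 8] = g22 / (g22 + r22)
            kept += 1

    return out, kept, err_cycle, jitter_count
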