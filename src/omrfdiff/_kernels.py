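"""Inner-loop kernels for the Metropolis-within-Gibbs sampler.

State layout (per group): the response matrix ``X`` (n x p ints), the rest
scores ``R = X @ sigma_g``, their exponentials ``E = exp(R)``, and the
full-conditional normalizers ``N[t, i] = 1 + sum_c exp(mu_ic) E[t, i]^c``.
With these caches a block update needs no per-row transcendentals:

* the *numerator* change of the column log-pseudolikelihood is a constant
  times a sufficient statistic (category counts for threshold moves,
  ``sum_t x_i x_j`` for interaction moves);
* the *normalizer* change is ``-sum_t log(N_new/N_old)``, evaluated as
  chunked products with one log per chunk.

``E``/``N`` are updated multiplicatively on acceptance and refreshed from
``R`` periodically to stop floating-point drift.  Overflowing proposals give
a -inf acceptance ratio (rejection), so current states stay finite.

Compiled with numba when available; the pure-Python fallback is functional
but slow and intended only for debugging.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    NUMBA = True
except ImportError:  # pragma: no cover
    NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)
_CHUNK = 8


@njit(cache=True)
def _log_betaprime_kernel(mu, a, b, lbeta):
    # log-density of mu with exp(mu) ~ BetaPrime(a,b); lbeta = log B(a,b)
    if mu > 0.0:
        sp = mu + np.log1p(np.exp(-mu))
    else:
        sp = np.log1p(np.exp(mu))
    return a * mu - (a + b) * sp - lbeta


@njit(cache=True)
def _log_cauchy_kernel(x, scale):
    return -np.log(np.pi * scale) - np.log1p((x / scale) ** 2)


@njit(cache=True)
def _log_normal_kernel(x, sd):
    return -_LOG_SQRT_2PI - np.log(sd) - 0.5 * (x / sd) ** 2


@njit(cache=True)
def _rm_update(sd, accepted, step, target, decay, sd_min, sd_max):
    # Robbins-Monro on log sd, clipped to bounds
    g = step ** (-decay)
    new = sd * np.exp(g * (accepted - target))
    if new < sd_min:
        new = sd_min
    elif new > sd_max:
        new = sd_max
    return new


@njit(cache=True)
def col_ll(X, R, col, mu, m):
    """Reference column log-pseudolikelihood (init/refresh/debug path)."""
    n = X.shape[0]
    emu = np.empty(m)
    for c in range(m):
        emu[c] = np.exp(mu[c])
    tot = 0.0
    for t in range(n):
        r = R[t, col]
        e = np.exp(r)
        s = 1.0
        tc = 1.0
        for c in range(1, m + 1):
            tc *= e
            s += emu[c - 1] * tc
        xc = X[t, col]
        if xc > 0:
            tot += mu[xc - 1] + xc * r
        tot -= np.log(s)
    return tot


@njit(cache=True)
def refresh_caches(X, R, E, N, mu, ncat):
    """Recompute E = exp(R) and the normalizers N from scratch."""
    n, p = R.shape
    for i in range(p):
        m = ncat[i] - 1
        emu = np.empty(m)
        for c in range(m):
            emu[c] = np.exp(mu[i, c])
        for t in range(n):
            e = np.exp(R[t, i])
            E[t, i] = e
            s = 1.0
            tc = 1.0
            for c in range(1, m + 1):
                tc *= e
                s += emu[c - 1] * tc
            N[t, i] = s


@njit(cache=True)
def _dll_norm_thr_scalar(E, N, sn, col, c, demu):
    """-sum_t log(N_new/N_old) for a single-threshold move.

    N_new = N_old + demu * E^c is written into ``sn`` for reuse on accept.
    """
    n = E.shape[0]
    tot = 0.0
    prod = 1.0
    k = 0
    for t in range(n):
        e = E[t, col]
        ec = e
        for _ in range(c - 1):
            ec *= e
        s_new = N[t, col] + demu * ec
        sn[t] = s_new
        prod *= s_new / N[t, col]
        k += 1
        if k == _CHUNK:
            tot -= np.log(prod)
            prod = 1.0
            k = 0
    if k > 0:
        tot -= np.log(prod)
    return tot


@njit(cache=True)
def _dll_norm_thr_vector(E, N, sn, col, emu_new, m):
    """-sum_t log(N_new/N_old) when the whole threshold vector changes."""
    n = E.shape[0]
    tot = 0.0
    prod = 1.0
    k = 0
    for t in range(n):
        e = E[t, col]
        s = 1.0
        tc = 1.0
        for c in range(1, m + 1):
            tc *= e
            s += emu_new[c - 1] * tc
        sn[t] = s
        prod *= s / N[t, col]
        k += 1
        if k == _CHUNK:
            tot -= np.log(prod)
            prod = 1.0
            k = 0
    if k > 0:
        tot -= np.log(prod)
    return tot


@njit(cache=True)
def _dll_norm_interaction(E, N, sn, X, col, other, emu, m, f):
    """-sum_t log(N_new/N_old) when the rest score of `col` shifts by
    d * x_other; f[v] = exp(d * v) precomputed over category values."""
    n = E.shape[0]
    tot = 0.0
    prod = 1.0
    k = 0
    for t in range(n):
        e = E[t, col] * f[X[t, other]]
        s = 1.0
        tc = 1.0
        for c in range(1, m + 1):
            tc *= e
            s += emu[c - 1] * tc
        sn[t] = s
        prod *= s / N[t, col]
        k += 1
        if k == _CHUNK:
            tot -= np.log(prod)
            prod = 1.0
            k = 0
    if k > 0:
        tot -= np.log(prod)
    return tot


@njit(cache=True)
def _apply_interaction(E, N, R, X, col, other, sn, f, d):
    n = E.shape[0]
    for t in range(n):
        E[t, col] *= f[X[t, other]]
        N[t, col] = sn[t]
        R[t, col] += d * X[t, other]


@njit(cache=True)
def upd_thresholds_lockstep(mu1, mu2, ncat, cnt1, cnt2,
                            E1, N1, sn1, E2, N2, sn2,
                            sd, z, u, a, b, lbeta,
                            adapt, step, target, decay, sd_min, sd_max, acc):
    """Overall-threshold scalar updates: both groups shift together."""
    p = ncat.shape[0]
    k = 0
    for i in range(p):
        m = ncat[i] - 1
        for c0 in range(m):
            c = c0 + 1
            d = sd[i, c0] * z[k]
            ov = 0.5 * (mu1[i, c0] + mu2[i, c0])
            dlp = (_log_betaprime_kernel(ov + d, a, b, lbeta)
                   - _log_betaprime_kernel(ov, a, b, lbeta))
            demu1 = np.exp(mu1[i, c0] + d) - np.exp(mu1[i, c0])
            demu2 = np.exp(mu2[i, c0] + d) - np.exp(mu2[i, c0])
            logA = (d * (cnt1[i, c0] + cnt2[i, c0]) + dlp
                    + _dll_norm_thr_scalar(E1, N1, sn1, i, c, demu1)
                    + _dll_norm_thr_scalar(E2, N2, sn2, i, c, demu2))
            ok = np.log(u[k]) < logA
            if ok:
                mu1[i, c0] += d
                mu2[i, c0] += d
                for t in range(E1.shape[0]):
                    N1[t, i] = sn1[t]
                for t in range(E2.shape[0]):
                    N2[t, i] = sn2[t]
                acc[0] += 1
            if adapt:
                sd[i, c0] = _rm_update(sd[i, c0], 1.0 if ok else 0.0, step,
                                       target, decay, sd_min, sd_max)
            k += 1


@njit(cache=True)
def upd_thresholds_onegroup(mu, ncat, cnt, E, N, sn,
                            sd, z, u, a, b, lbeta,
                            adapt, step, target, decay, sd_min, sd_max, acc):
    """Free-mode group-specific threshold updates (beta-prime prior)."""
    p = ncat.shape[0]
    k = 0
    for i in range(p):
        m = ncat[i] - 1
        for c0 in range(m):
            c = c0 + 1
            d = sd[i, c0] * z[k]
            dlp = (_log_betaprime_kernel(mu[i, c0] + d, a, b, lbeta)
                   - _log_betaprime_kernel(mu[i, c0], a, b, lbeta))
            demu = np.exp(mu[i, c0] + d) - np.exp(mu[i, c0])
            logA = (d * cnt[i, c0] + dlp
                    + _dll_norm_thr_scalar(E, N, sn, i, c, demu))
            ok = np.log(u[k]) < logA
            if ok:
                mu[i, c0] += d
                for t in range(E.shape[0]):
                    N[t, i] = sn[t]
                acc[0] += 1
            if adapt:
                sd[i, c0] = _rm_update(sd[i, c0], 1.0 if ok else 0.0, step,
                                       target, decay, sd_min, sd_max)
            k += 1


@njit(cache=True)
def upd_threshold_diffs(mu1, mu2, gamma_thr, ncat, cnt1, cnt2,
                        E1, N1, sn1, E2, N2, sn2,
                        sd, z, u, slab_scale, force,
                        adapt, step, target, decay, sd_min, sd_max, acc):
    """Within-model move of a whole threshold-difference vector per variable.

    delta_i = mu2[i] - mu1[i] gets a joint diagonal-Gaussian step with the
    overall thresholds (mu1+mu2)/2 held fixed; Cauchy slab prior per
    component.
    """
    p = ncat.shape[0]
    k = 0
    for i in range(p):
        m = ncat[i] - 1
        if (not force) and gamma_thr[i] == 0:
            k += m
            continue
        new1 = np.empty(m)
        new2 = np.empty(m)
        emu1 = np.empty(m)
        emu2 = np.empty(m)
        dlp = 0.0
        num = 0.0
        for c0 in range(m):
            ov = 0.5 * (mu1[i, c0] + mu2[i, c0])
            cur = mu2[i, c0] - mu1[i, c0]
            new = cur + sd[i, c0] * z[k + c0]
            new1[c0] = ov - 0.5 * new
            new2[c0] = ov + 0.5 * new
            emu1[c0] = np.exp(new1[c0])
            emu2[c0] = np.exp(new2[c0])
            dlp += (_log_cauchy_kernel(new, slab_scale)
                    - _log_cauchy_kernel(cur, slab_scale))
            num += ((new1[c0] - mu1[i, c0]) * cnt1[i, c0]
                    + (new2[c0] - mu2[i, c0]) * cnt2[i, c0])
        logA = (num + dlp
                + _dll_norm_thr_vector(E1, N1, sn1, i, emu1, m)
                + _dll_norm_thr_vector(E2, N2, sn2, i, emu2, m))
        ok = np.log(u[i]) < logA
        if ok:
            for c0 in range(m):
                mu1[i, c0] = new1[c0]
                mu2[i, c0] = new2[c0]
            for t in range(E1.shape[0]):
                N1[t, i] = sn1[t]
            for t in range(E2.shape[0]):
                N2[t, i] = sn2[t]
            acc[0] += 1
        if adapt:
            for c0 in range(m):
                sd[i, c0] = _rm_update(sd[i, c0], 1.0 if ok else 0.0, step,
                                       target, decay, sd_min, sd_max)
        k += m


@njit(cache=True)
def _interaction_dll(d1, d2, e, pair_i, pair_j, mu1, mu2, ncat1, ncat2,
                     X1, S1, E1, N1, sni1, snj1, R1,
                     X2, S2, E2, N2, sni2, snj2, R2, mmax):
    """Joint log-pseudolikelihood change when pair `e` shifts by d1/d2."""
    i = pair_i[e]
    j = pair_j[e]
    vmax = mmax + 1
    f1 = np.empty(vmax)
    f2 = np.empty(vmax)
    for v in range(vmax):
        f1[v] = np.exp(d1 * v)
        f2[v] = np.exp(d2 * v)
    m1i = ncat1[i] - 1
    m1j = ncat1[j] - 1
    m2i = ncat2[i] - 1
    m2j = ncat2[j] - 1
    emu1i = np.exp(mu1[i, :m1i])
    emu1j = np.exp(mu1[j, :m1j])
    emu2i = np.exp(mu2[i, :m2i])
    emu2j = np.exp(mu2[j, :m2j])
    dll = 2.0 * (d1 * S1[e] + d2 * S2[e])
    dll += _dll_norm_interaction(E1, N1, sni1, X1, i, j, emu1i, m1i, f1)
    dll += _dll_norm_interaction(E1, N1, snj1, X1, j, i, emu1j, m1j, f1)
    dll += _dll_norm_interaction(E2, N2, sni2, X2, i, j, emu2i, m2i, f2)
    dll += _dll_norm_interaction(E2, N2, snj2, X2, j, i, emu2j, m2j, f2)
    return dll, f1, f2


@njit(cache=True)
def _interaction_apply(d1, d2, e, pair_i, pair_j, f1, f2,
                       X1, E1, N1, sni1, snj1, R1,
                       X2, E2, N2, sni2, snj2, R2, s1, s2):
    i = pair_i[e]
    j = pair_j[e]
    _apply_interaction(E1, N1, R1, X1, i, j, sni1, f1, d1)
    _apply_interaction(E1, N1, R1, X1, j, i, snj1, f1, d1)
    _apply_interaction(E2, N2, R2, X2, i, j, sni2, f2, d2)
    _apply_interaction(E2, N2, R2, X2, j, i, snj2, f2, d2)
    s1[e] += d1
    s2[e] += d2


@njit(cache=True)
def upd_interactions(s1, s2, pair_i, pair_j, which, mu1, mu2, ncat1, ncat2,
                     X1, S1, E1, N1, sni1, snj1, R1,
                     X2, S2, E2, N2, sni2, snj2, R2,
                     gamma_int, sd, z, u, prior_scale, force,
                     adapt, step, target, decay, sd_min, sd_max, acc, mmax):
    """Scalar interaction updates.

    ``which`` = 0: overall move (both groups shift by d, Cauchy prior on the
    overall value).  ``which`` = 1: difference move (groups shift by -/+ d/2,
    Cauchy slab on the contrast; skipped when the indicator is 0 unless
    ``force``).
    """
    npair = pair_i.shape[0]
    for e in range(npair):
        if which == 1 and (not force) and gamma_int[e] == 0:
            continue
        d = sd[e] * z[e]
        if which == 0:
            d1 = d
            d2 = d
            ov = 0.5 * (s1[e] + s2[e])
            dlp = (_log_cauchy_kernel(ov + d, prior_scale)
                   - _log_cauchy_kernel(ov, prior_scale))
        else:
            d1 = -0.5 * d
            d2 = 0.5 * d
            cur = s2[e] - s1[e]
            dlp = (_log_cauchy_kernel(cur + d, prior_scale)
                   - _log_cauchy_kernel(cur, prior_scale))
        dll, f1, f2 = _interaction_dll(
            d1, d2, e, pair_i, pair_j, mu1, mu2, ncat1, ncat2,
            X1, S1, E1, N1, sni1, snj1, R1,
            X2, S2, E2, N2, sni2, snj2, R2, mmax)
        ok = np.log(u[e]) < dll + dlp
        if ok:
            _interaction_apply(d1, d2, e, pair_i, pair_j, f1, f2,
                               X1, E1, N1, sni1, snj1, R1,
                               X2, E2, N2, sni2, snj2, R2, s1, s2)
            acc[0] += 1
        if adapt:
            sd[e] = _rm_update(sd[e], 1.0 if ok else 0.0, step,
                               target, decay, sd_min, sd_max)


@njit(cache=True)
def flip_interaction_indicators(s1, s2, gamma_int, pair_i, pair_j,
                                mu1, mu2, ncat1, ncat2,
                                X1, S1, E1, N1, sni1, snj1, R1,
                                X2, S2, E2, N2, sni2, snj2, R2,
                                sd, z, u, slab_scale,
                                prior_type, prior_a, prior_b, acc, mmax):
    """Joint indicator+parameter flips for interaction differences.

    0 -> 1 draws the difference from the tuned Gaussian proposal centered at
    zero and accepts with pseudolikelihood x slab / proposal density times
    the conditional prior odds of inclusion; 1 -> 0 is the reverse move and
    resets both group values to their average (difference exactly zero).
    ``prior_type`` 0 = Bernoulli(prior_a); 1 = BetaBernoulli(prior_a, prior_b).
    """
    npair = pair_i.shape[0]
    for e in range(npair):
        k_other = 0
        for f in range(npair):
            if f != e and gamma_int[f] == 1:
                k_other += 1
        if prior_type == 0:
            lpo = np.log(prior_a) - np.log1p(-prior_a)
        else:
            lpo = np.log(prior_a + k_other) - np.log(prior_b + npair - 1 - k_other)
        if gamma_int[e] == 0:
            dstar = sd[e] * z[e]
            d1 = -0.5 * dstar
            d2 = 0.5 * dstar
            extra = (_log_cauchy_kernel(dstar, slab_scale)
                     - _log_normal_kernel(dstar, sd[e]) + lpo)
        else:
            cur = s2[e] - s1[e]
            d1 = 0.5 * cur
            d2 = -0.5 * cur
            extra = (-_log_cauchy_kernel(cur, slab_scale)
                     + _log_normal_kernel(cur, sd[e]) - lpo)
        dll, f1, f2 = _interaction_dll(
            d1, d2, e, pair_i, pair_j, mu1, mu2, ncat1, ncat2,
            X1, S1, E1, N1, sni1, snj1, R1,
            X2, S2, E2, N2, sni2, snj2, R2, mmax)
        if np.log(u[e]) < dll + extra:
            _interaction_apply(d1, d2, e, pair_i, pair_j, f1, f2,
                               X1, E1, N1, sni1, snj1, R1,
                               X2, E2, N2, sni2, snj2, R2, s1, s2)
            if gamma_int[e] == 0:
                gamma_int[e] = 1
            else:
                gamma_int[e] = 0
                ov = 0.5 * (s1[e] + s2[e])
                s1[e] = ov
                s2[e] = ov
            acc[0] += 1


@njit(cache=True)
def flip_threshold_indicators(mu1, mu2, gamma_thr, ncat, cnt1, cnt2,
                              E1, N1, sn1, E2, N2, sn2,
                              sd, z, u, slab_scale,
                              prior_type, prior_a, prior_b, acc):
    """Joint indicator+vector flips for threshold-difference vectors."""
    p = ncat.shape[0]
    k = 0
    for i in range(p):
        m = ncat[i] - 1
        k_other = 0
        for f in range(p):
            if f != i and gamma_thr[f] == 1:
                k_other += 1
        if prior_type == 0:
            lpo = np.log(prior_a) - np.log1p(-prior_a)
        else:
            lpo = np.log(prior_a + k_other) - np.log(prior_b + p - 1 - k_other)
        new1 = np.empty(m)
        new2 = np.empty(m)
        emu1 = np.empty(m)
        emu2 = np.empty(m)
        extra = 0.0
        num = 0.0
        if gamma_thr[i] == 0:
            for c0 in range(m):
                ov = 0.5 * (mu1[i, c0] + mu2[i, c0])
                dstar = sd[i, c0] * z[k + c0]
                new1[c0] = ov - 0.5 * dstar
                new2[c0] = ov + 0.5 * dstar
                extra += (_log_cauchy_kernel(dstar, slab_scale)
                          - _log_normal_kernel(dstar, sd[i, c0]))
            extra += lpo
        else:
            for c0 in range(m):
                ov = 0.5 * (mu1[i, c0] + mu2[i, c0])
                cur = mu2[i, c0] - mu1[i, c0]
                new1[c0] = ov
                new2[c0] = ov
                extra += (-_log_cauchy_kernel(cur, slab_scale)
                          + _log_normal_kernel(cur, sd[i, c0]))
            extra -= lpo
        for c0 in range(m):
            emu1[c0] = np.exp(new1[c0])
            emu2[c0] = np.exp(new2[c0])
            num += ((new1[c0] - mu1[i, c0]) * cnt1[i, c0]
                    + (new2[c0] - mu2[i, c0]) * cnt2[i, c0])
        logA = (num + extra
                + _dll_norm_thr_vector(E1, N1, sn1, i, emu1, m)
                + _dll_norm_thr_vector(E2, N2, sn2, i, emu2, m))
        if np.log(u[i]) < logA:
            gamma_thr[i] = 1 - gamma_thr[i]
            for c0 in range(m):
                mu1[i, c0] = new1[c0]
                mu2[i, c0] = new2[c0]
            for t in range(E1.shape[0]):
                N1[t, i] = sn1[t]
            for t in range(E2.shape[0]):
                N2[t, i] = sn2[t]
            acc[0] += 1
        k += m
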