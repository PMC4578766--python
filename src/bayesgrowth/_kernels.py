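"""Scalar likelihood kernel for the sampler hot loop.

Same mathematics as :mod:`bayesgrowth.likelihood` (Baranyi–Roberts
prediction, Gaussian points, censored uniform-plus-tail points), written as
a tight scalar loop so that numba can compile it; a numpy closure in
``likelihood.make_curve_loglik`` is the fallback when numba is missing.
Parameters arrive on the log10 scale and are converted internally.
"""

from __future__ import annotations

import numpy as np

__all__ = ["curve_loglik_kernel", "HAVE_NUMBA"]

_LN10 = 2.302585092994046
_LOG_SQRT_2PI = 0.9189385332046727


def _curve_loglik_py(times, values, cens, thr, inv_tail2, y0, mu, h0, ymax, sigma):
    if not (ymax > y0) or mu <= 0.0 or sigma <= 0.0 or h0 < 0.0:
        return -np.inf
    mu_ln = mu * _LN10
    g = (ymax - y0) * _LN10
    total = 0.0
    n_unc = 0
    ssr = 0.0
    for i in range(times.shape[0]):
        t = times[i]
        if h0 == 0.0:
            a = t
        elif t == 0.0:
            a = 0.0
        else:
            mt = mu_ln * t
            b = h0 - mt
            m = b if b > 0.0 else 0.0
            a = t - h0 / mu_ln + (
                m + np.log(np.exp(-m) - np.exp(-mt - m) + np.exp(b - m))
            ) / mu_ln
        me = mu_ln * a
        if g == np.inf:
            pred = y0 + me / _LN10
        else:
            big = g if g > me else me
            arg = np.exp(g - big) + np.exp(me - big) - np.exp(-big)
            if arg < 1e-300:
                arg = 1e-300
            pred = y0 + (g + me - big - np.log(arg)) / _LN10
        if cens[i]:
            ex = pred - thr
            if ex > 0.0:
                total -= inv_tail2 * ex * ex
            total -= np.log(thr)
        else:
            r = values[i] - pred
            ssr += r * r
            n_unc += 1
    total += -n_unc * (np.log(sigma) + _LOG_SQRT_2PI) - 0.5 * ssr / (sigma * sigma)
    return total


def _make_pair_kernel(curve_kernel):
    def _pair_loglik(
        t_a, v_a, c_a, thr_a, t_b, v_b, c_b, thr_b, inv_tail2, idx, isig, sigma_fixed, theta
    ):
        """Two-curve joint log-likelihood with parameter tying.

        ``idx`` holds the positions of (y0, mu_max, h0, ymax) for curve A then
        curve B inside ``theta``; ``isig`` the shared-noise position (or -1
        when the noise level is prescribed at ``sigma_fixed``).
        """
        sigma = theta[isig] if isig >= 0 else sigma_fixed
        la = curve_kernel(
            t_a, v_a, c_a, thr_a, inv_tail2,
            theta[idx[0]], theta[idx[1]], theta[idx[2]], theta[idx[3]], sigma,
        )
        if la == -np.inf or t_b.shape[0] == 0:
            return la
        return la + curve_kernel(
            t_b, v_b, c_b, thr_b, inv_tail2,
            theta[idx[4]], theta[idx[5]], theta[idx[6]], theta[idx[7]], sigma,
        )

    return _pair_loglik


try:  # compiled fast path
    from numba import njit

    curve_loglik_kernel = njit(cache=True)(_curve_loglik_py)
    pair_loglik_kernel = njit(cache=True)(_make_pair_kernel(curve_loglik_kernel))
    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba always present in CI image
    curve_loglik_kernel = _curve_loglik_py
    pair_loglik_kernel = _make_pair_kernel(curve_loglik_kernel)
    HAVE_NUMBA = False

__all__.append("pair_loglik_kernel")
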