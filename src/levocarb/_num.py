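"""Vectorised numerical kernels for the transit-absorption PK model.

The structural model is linear and time-invariant: each parallel absorption
chain delivers drug to the central compartment as an Erlang-density input
(shape ``m = n + 1``, rate ``ktr = (n + 1) / MTT``), and the disposition
impulse response is a sum of one or two exponentials.  The concentration
profile is therefore an exact finite sum of Erlang-by-exponential
convolutions; no ODE integration is required.  Everything here broadcasts
over a leading subject axis so that whole cohorts are evaluated in one pass.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammainc, gammaln

__all__ = ["disposition_terms", "erlang_exp_conv", "profile_conc"]

_X_NEG = -40.0  # series/closed-form switch for negative arguments


def disposition_terms(cl, vc, q=None, vp=None):
    """Exponential decomposition of the central-compartment impulse response.

    Returns ``(lams, coefs)`` with a trailing axis over exponential terms,
    such that the central *amount* after a unit bolus into the central
    compartment is ``sum_i coefs[..., i] * exp(-lams[..., i] * t)``.
    ``lams`` is sorted descending, so ``lams[..., -1]`` is the terminal
    slope.  One-compartment disposition when ``q``/``vp`` are ``None``.
    """
    cl = np.asarray(cl, dtype=float)
    vc = np.asarray(vc, dtype=float)
    k10 = cl / vc
    if q is None:
        lams = k10[..., None]
        return lams, np.ones_like(lams)
    q = np.asarray(q, dtype=float)
    vp = np.asarray(vp, dtype=float)
    k12 = q / vc
    k21 = q / vp
    s = k10 + k12 + k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
    # exact repeated roots are a measure-zero configuration; nudge apart
    disc = np.maximum(disc, 1e-10 * s)
    l1 = 0.5 * (s + disc)
    l2 = 0.5 * (s - disc)
    a1 = (l1 - k21) / (l1 - l2)
    a2 = (k21 - l2) / (l1 - l2)
    return np.stack([l1, l2], axis=-1), np.stack([a1, a2], axis=-1)


def erlang_exp_conv(tau, m, ktr, lam):
    """``I(tau) = ∫_0^tau Erlang(s; m, ktr) · exp(-lam·(tau-s)) ds``.

    ``m`` is a positive integer (transit compartments + 1) or an integer
    array; all arguments broadcast.  The result lies in ``[0, 1]`` and is
    the central-compartment response to a unit dose entering one transit
    chain, eliminated at rate ``lam``.

    Regimes on ``x = (ktr - lam)·tau``: positive ``x`` is evaluated in log
    space through the regularised lower incomplete gamma (exact and
    cancellation-free); moderately negative ``x`` uses a globally
    convergent power series; strongly negative ``x`` the two-term closed
    form ``(ktr/(ktr-lam))^m (e^{-lam·tau} - e^{-ktr·tau} Σ_{j<m} x^j/j!)``.
    """
    m = np.asarray(m)
    if np.any(m < 1):
        raise ValueError("m must be a positive integer")
    m_max = int(np.max(m))
    with np.errstate(all="ignore"):
        tau = np.asarray(tau, dtype=float)
        ktr = np.asarray(ktr, dtype=float)
        lam = np.asarray(lam, dtype=float)
        x = (ktr - lam) * tau
        kt = ktr * tau
        pos = tau > 0.0

        grow_all = bool(np.all((x > 1e-12) | ~pos))
        grow_val = np.exp(
            -lam * tau + m * (np.log(kt) - np.log(x)) + np.log(gammainc(m, x))
        )
        if grow_all:
            out = np.where(pos, grow_val, 0.0)
            return np.clip(np.broadcast_to(out, np.broadcast(tau, ktr, lam, m).shape), 0.0, None)

        out = np.zeros(np.broadcast(tau, ktr, lam, m).shape)
        tau, m, ktr, lam, x, kt = np.broadcast_arrays(tau, m, ktr, lam, x, kt)
        grow = pos & (x > 1e-12)
        out[grow] = np.broadcast_to(grow_val, out.shape)[grow]

        # ktr == lam: analytic limit
        mid = pos & (np.abs(x) <= 1e-12)
        if np.any(mid):
            out[mid] = np.exp(
                m[mid] * np.log(kt[mid]) - kt[mid] - gammaln(m[mid] + 1)
            )

        # moderately negative x: globally convergent power series
        small = pos & (x > _X_NEG) & (x < -1e-12)
        if np.any(small):
            xs = x[small]
            ms = m[small]
            # factorial growth only overtakes |x|^j beyond j ~ e·|x|
            n_terms = int(3.0 * np.ceil(np.max(np.abs(xs)))) + 40
            term = np.exp(-gammaln(ms + 1))
            series = term.copy()
            for j in range(1, n_terms + 1):
                term = term * xs / (ms + j)
                series += term
            out[small] = np.exp(ms * np.log(kt[small]) - kt[small]) * series

        # strongly negative x: two-term closed form (no cancellation there)
        big = pos & (x <= _X_NEG)
        if np.any(big):
            xb = x[big]
            mb = m[big]
            poly = np.ones_like(xb)
            term = np.ones_like(xb)
            for j in range(1, m_max):
                term = term * xb / j
                poly = np.where(j < mb, poly + term, poly)
            delta = ktr[big] - lam[big]
            out[big] = (ktr[big] / delta) ** mb * (
                np.exp(-lam[big] * tau[big]) - np.exp(-kt[big]) * poly
            )

    return np.clip(out, 0.0, None)


def profile_conc(times, dose_t, dose_a, params, n1, n2, two_compartment):
    """Concentration profiles for a batch of subjects.

    Parameters
    ----------
    times : array (..., T) of observation times (min).
    dose_t, dose_a : arrays (..., D) of dose times (min) and amounts (mg).
        Pad unused dose slots with amount 0.
    params : mapping with arrays broadcastable to the subject shape ``(...)``:
        ``cl_f, vc_f, mtt1, mtt2, fa1, f_rel, c0`` and, for two-compartment
        disposition, ``q_f, vp_f``.  ``cl_f`` (and the derived disposition
        terms) may alternatively carry a trailing per-dose axis ``(..., D)``
        to express dose-specific clearance (used by the cumulative-carbidopa
        convention in external evaluation).
    n1, n2 : transit-compartment counts of the fast and slow chain.
    two_compartment : whether disposition has a peripheral compartment.

    Returns
    -------
    conc : array (..., T) in µg/mL (mg/L).  Includes the pre-dose baseline
        ``c0 · exp(-lambda_z · (t - t_first_dose))`` evaluated at every
        requested time (back-extrapolated before the first dose).
    """
    times = np.asarray(times, dtype=float)
    dose_t = np.atleast_1d(np.asarray(dose_t, dtype=float))
    dose_a = np.atleast_1d(np.asarray(dose_a, dtype=float))
    D = dose_t.shape[-1]

    def per_dose(name):
        v = np.asarray(params[name], dtype=float)
        if v.ndim and v.shape[-1] == D and D > 1:
            return v
        return v[..., None]

    with np.errstate(all="ignore"):
        cl = per_dose("cl_f")
        vc = np.asarray(params["vc_f"], dtype=float)
        if two_compartment:
            lams, coefs = disposition_terms(
                cl, vc[..., None], per_dose("q_f"), per_dose("vp_f")
            )
        else:
            lams, coefs = disposition_terms(cl, vc[..., None])
        n_exp = lams.shape[-1]
        # lams/coefs: (..., Dp, E) with Dp in {1, D}

        tau = times[..., None, :] - dose_t[..., :, None]  # (..., D, T)
        fa1 = np.asarray(params["fa1"], dtype=float)[..., None, None]
        ktr1 = (n1 + 1) / np.asarray(params["mtt1"], dtype=float)[..., None, None]
        ktr2 = (n2 + 1) / np.asarray(params["mtt2"], dtype=float)[..., None, None]

        # one fused kernel call over all chain x exponential combinations,
        # stacked along a new leading axis
        pad = (1,) * tau.ndim
        m_stack = np.array([n1 + 1] * n_exp + [n2 + 1] * n_exp).reshape(
            (2 * n_exp,) + pad
        )
        ktr_stack = np.stack([ktr1] * n_exp + [ktr2] * n_exp, axis=0)
        lam_list = [lams[..., :, e][..., None] for e in range(n_exp)]
        lam_stack = np.stack(lam_list * 2, axis=0)
        w_list = [coefs[..., :, e][..., None] for e in range(n_exp)]
        w_stack = np.stack(
            [fa1 * w for w in w_list] + [(1.0 - fa1) * w for w in w_list], axis=0
        )
        conv = erlang_exp_conv(tau[None], m_stack, ktr_stack, lam_stack)
        acc = np.sum(w_stack * conv, axis=0)

        f_rel = np.asarray(params["f_rel"], dtype=float)
        central = np.sum((dose_a * f_rel[..., None])[..., :, None] * acc, axis=-2)
        conc = central / vc[..., None]

        c0 = np.asarray(params["c0"], dtype=float)
        lam_z = lams[..., -1, -1]  # smallest exponent of the last dose block
        t0 = np.min(dose_t, axis=-1)
        conc = conc + c0[..., None] * np.exp(
            -lam_z[..., None] * (times - t0[..., None])
        )
    return conc
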