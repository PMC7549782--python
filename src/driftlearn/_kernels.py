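"""Jitted numerical cores for the hierarchical sampler.

Private module.  Holds numba-compiled implementations of the per-trial
likelihoods (mirroring :mod:`driftlearn.learning_models`, which is the
readable reference semantics), the group-prior densities, and the full
adaptive random-walk Metropolis-within-Gibbs chain loop.  Everything
here works on flat float64/int64 arrays; parameter packing/unpacking
lives in :mod:`driftlearn.hierarchical_fit`.

Parameter layout conventions (shared with hierarchical_fit):

* unit-interval parameters ``u`` (beta group priors), in order:
  model parameters first (RL: [alpha]; RL2: [alpha+, alpha-]; KF: [];
  PH: [assoc_init, decay, kappa]) then decision parameters
  (constant: [beta]; dynamic: [theta, c_raw] with c = 4*c_raw - 2).
* variance parameters ``v`` (half-Cauchy group priors), in order:
  KF: [drift_var, init_prior_var]; estimation-task fits append the
  per-participant reporting variance as the last slot.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# model ids
RL, RL2, KF, PH = 0, 1, 2, 3
# decision ids
DEC_NONE, DEC_CONST, DEC_DYN = 0, 1, 2
# task ids
TASK_EST, TASK_CHOICE = 0, 1

N_UNIT_MODEL = {RL: 1, RL2: 2, KF: 0, PH: 3}
N_VAR_MODEL = {RL: 0, RL2: 0, KF: 2, PH: 0}
N_UNIT_DEC = {DEC_NONE: 0, DEC_CONST: 1, DEC_DYN: 2}

_LOG2PI = math.log(2.0 * math.pi)
_LOG_2_OVER_PI = math.log(2.0 / math.pi)


@njit(cache=True)
def _betaln(a, b):
    return math.lgamma(a) + math.lgamma(b) - math.lgamma(a + b)


@njit(cache=True)
def beta_logpdf_mn(x, m, n):
    """log Beta(x; a=m*n, b=(1-m)*n) — mean/precision parameterization."""
    if x <= 0.0 or x >= 1.0:
        return -np.inf
    a = m * n
    b = (1.0 - m) * n
    return (a - 1.0) * math.log(x) + (b - 1.0) * math.log1p(-x) - _betaln(a, b)


@njit(cache=True)
def halfcauchy_logpdf(x, scale):
    if x < 0.0:
        return -np.inf
    z = x / scale
    return _LOG_2_OVER_PI - math.log(scale) - math.log1p(z * z)


@njit(cache=True)
def participant_loglik(
    model_id, decision_id, task_id, u, v, outcome, estimate, choice, tib, beta_scale
):
    """Log-likelihood of one participant's trial sequence.

    Arrays are that participant's trials, sorted by (block, trial);
    ``tib`` is the 1-based trial index within its block (tib == 1 resets
    the learner state).
    """
    ll = 0.0
    n = outcome.shape[0]
    nu_model = 0
    if model_id == RL:
        nu_model = 1
    elif model_id == RL2:
        nu_model = 2
    elif model_id == PH:
        nu_model = 3

    if task_id == TASK_EST:
        rv = v[v.shape[0] - 1]  # reporting variance, last variance slot
        const = -0.5 * (_LOG2PI + math.log(rv))
        e = 0.0
        s2 = 0.0
        assoc = 0.0
        for j in range(n):
            if tib[j] == 1:
                e = estimate[j]  # expectation initialized to first prediction
                if model_id == KF:
                    s2 = v[1]
                elif model_id == PH:
                    assoc = u[0]
            resid = estimate[j] - e
            ll += const - resid * resid / (2.0 * rv)
            pe = outcome[j] - e
            if model_id == RL:
                e += u[0] * pe
            elif model_id == RL2:
                if pe >= 0.0:
                    e += u[0] * pe
                else:
                    e += u[1] * pe
            elif model_id == KF:
                g = s2 / (1.0 + s2)
                e += g * pe
                s2 = s2 / (1.0 + s2) + v[0]
            else:  # PH
                lr = u[2] * assoc
                if lr > 1.0:
                    lr = 1.0
                e += lr * pe
                assoc = u[1] * abs(pe) + (1.0 - u[1]) * assoc
        return ll

    # choice task: two options, expectations start at 50
    e0 = 50.0
    e1 = 50.0
    s20 = 0.0
    s21 = 0.0
    a0 = 0.0
    a1 = 0.0
    for j in range(n):
        if tib[j] == 1:
            e0 = 50.0
            e1 = 50.0
            if model_id == KF:
                s20 = v[1]
                s21 = v[1]
            elif model_id == PH:
                a0 = u[0]
                a1 = u[0]
        if decision_id == DEC_CONST:
            beta = beta_scale * u[nu_model]
        else:
            c = 4.0 * u[nu_model + 1] - 2.0
            beta = beta_scale * u[nu_model] * (tib[j] / 10.0) ** c
        ch = choice[j]
        if ch == 0:
            d = e0 - e1
        else:
            d = e1 - e0
        x = beta * d
        if x >= 0.0:
            ll += -math.log1p(math.exp(-x))
        else:
            ll += x - math.log1p(math.exp(x))
        # update chosen option only
        if ch == 0:
            pe = outcome[j] - e0
        else:
            pe = outcome[j] - e1
        if model_id == RL:
            upd = u[0] * pe
        elif model_id == RL2:
            upd = u[0] * pe if pe >= 0.0 else u[1] * pe
        elif model_id == KF:
            s2 = s20 if ch == 0 else s21
            g = s2 / (1.0 + s2)
            upd = g * pe
            s2 = s2 / (1.0 + s2) + v[0]
            if ch == 0:
                s20 = s2
            else:
                s21 = s2
        else:  # PH
            a = a0 if ch == 0 else a1
            lr = u[2] * a
            if lr > 1.0:
                lr = 1.0
            upd = lr * pe
            a = u[1] * abs(pe) + (1.0 - u[1]) * a
            if ch == 0:
                a0 = a
            else:
                a1 = a
        if ch == 0:
            e0 += upd
        else:
            e1 += upd
    return ll


@njit(cache=True)
def total_loglik(
    model_id,
    decision_id,
    task_id,
    starts,
    outcome,
    estimate,
    choice,
    tib,
    u2d,
    v2d,
    beta_scale,
):
    """Summed log-likelihood across participants at given parameter values."""
    total = 0.0
    n_part = starts.shape[0] - 1
    for i in range(n_part):
        lo = starts[i]
        hi = starts[i + 1]
        total += participant_loglik(
            model_id,
            decision_id,
            task_id,
            u2d[i],
            v2d[i],
            outcome[lo:hi],
            estimate[lo:hi],
            choice[lo:hi],
            tib[lo:hi],
            beta_scale,
        )
    return total


@njit(cache=True)
def deviance_draws(
    model_id,
    decision_id,
    task_id,
    starts,
    outcome,
    estimate,
    choice,
    tib,
    ind_u,
    ind_v,
    beta_scale,
):
    """Deviance (-2 log L) for every retained draw. ind_u: (R, N, nu)."""
    R = ind_u.shape[0]
    out = np.empty(R)
    for r in range(R):
        out[r] = -2.0 * total_loglik(
            model_id,
            decision_id,
            task_id,
            starts,
            outcome,
            estimate,
            choice,
            tib,
            ind_u[r],
            ind_v[r],
            beta_scale,
        )
    return out


@njit(cache=True)
def _sigmoid(x):
    if x >= 0.0:
        return 1.0 / (1.0 + math.exp(-x))
    z = math.exp(x)
    return z / (1.0 + z)


@njit(cache=True)
def _beta_logpdf_unnorm(x, a, b):
    if x <= 0.0 or x >= 1.0:
        return -np.inf
    return (a - 1.0) * math.log(x) + (b - 1.0) * math.log1p(-x)


@njit(cache=True)
def _group_logprior_i(xu, xv, beta_a, beta_b, beta_norm, scale):
    """Group-level log-density of one participant's parameters (natural
    scale), with the beta normalizers precomputed per hyperparameter."""
    lp = 0.0
    for k in range(xu.shape[0]):
        lp += _beta_logpdf_unnorm(xu[k], beta_a[k], beta_b[k]) - beta_norm[k]
    for k in range(xv.shape[0]):
        lp += halfcauchy_logpdf(xv[k], scale[k])
    return lp


LOG_PREC_LO = math.log(2.0)
LOG_PREC_HI = math.log(600.0)
SCALE_HI = 1000.0


@njit(cache=True)
def run_chain(
    seed,
    n_samples,
    burn_in,
    thin,
    model_id,
    decision_id,
    task_id,
    starts,
    outcome,
    estimate,
    choice,
    tib,
    beta_scale,
    m0,
    logn0,
    scale0,
    zu0,
    zv0,
):
    """One adaptive Metropolis-within-Gibbs chain.

    Individual parameters are updated jointly per participant via a
    random-walk proposal on transformed scales (logit for unit-interval,
    log for variance parameters); hyperparameters are updated one at a
    time.  Proposal step sizes adapt toward standard acceptance targets
    (0.23 for blocks, 0.44 for scalars) during burn-in only.

    Returns retained draws on the natural scale:
    (m, nprec, scale, ind_u, ind_v).
    """
    np.random.seed(seed)
    n_unit = m0.shape[0]
    n_var = scale0.shape[0]
    n_part = starts.shape[0] - 1

    m = m0.copy()
    logn = logn0.copy()
    logscale = np.log(scale0)
    zu = zu0.copy()
    zv = zv0.copy()

    # natural-scale caches
    xu = np.empty((n_part, n_unit))
    xv = np.empty((n_part, n_var))
    for i in range(n_part):
        for k in range(n_unit):
            xu[i, k] = _sigmoid(zu[i, k])
        for k in range(n_var):
            xv[i, k] = math.exp(zv[i, k])

    nprec = np.exp(logn)
    scale = np.exp(logscale)

    # cached per-participant log target: loglik + group prior + jacobians
    loglik_i = np.empty(n_part)
    for i in range(n_part):
        lo = starts[i]
        hi = starts[i + 1]
        loglik_i[i] = participant_loglik(
            model_id,
            decision_id,
            task_id,
            xu[i],
            xv[i],
            outcome[lo:hi],
            estimate[lo:hi],
            choice[lo:hi],
            tib[lo:hi],
            beta_scale,
        )

    step_ind = np.full(n_part, 0.3)
    step_m = np.full(n_unit, 0.5)
    step_n = np.full(n_unit, 0.5)
    step_s = np.full(n_var, 0.5)

    # per-dimension proposal shaping (adaptive-Metropolis style): running
    # mean/variance of each transformed coordinate, accumulated during
    # burn-in and frozen afterwards
    nd = n_unit + n_var
    run_mean = np.zeros((n_part, nd))
    run_m2 = np.zeros((n_part, nd))
    run_count = 0
    prop_sd = np.ones((n_part, nd))

    n_keep = (n_samples - burn_in) // thin
    out_m = np.empty((n_keep, n_unit))
    out_n = np.empty((n_keep, n_unit))
    out_s = np.empty((n_keep, n_var))
    out_u = np.empty((n_keep, n_part, n_unit))
    out_v = np.empty((n_keep, n_part, n_var))

    kept = 0
    for it in range(n_samples):
        adapt = it < burn_in
        c_t = min(0.25, 5.0 / ((it + 1.0) ** 0.7))

        # --- individual-parameter blocks ---
        beta_a = m * nprec
        beta_b = (1.0 - m) * nprec
        beta_norm = np.empty(n_unit)
        for k in range(n_unit):
            beta_norm[k] = _betaln(beta_a[k], beta_b[k])
        for i in range(n_part):
            lo = starts[i]
            hi = starts[i + 1]
            zu_prop = np.empty(n_unit)
            zv_prop = np.empty(n_var)
            xu_prop = np.empty(n_unit)
            xv_prop = np.empty(n_var)
            for k in range(n_unit):
                zu_prop[k] = zu[i, k] + step_ind[i] * prop_sd[i, k] * np.random.standard_normal()
                xu_prop[k] = _sigmoid(zu_prop[k])
            for k in range(n_var):
                zv_prop[k] = (
                    zv[i, k]
                    + step_ind[i] * prop_sd[i, n_unit + k] * np.random.standard_normal()
                )
                xv_prop[k] = math.exp(zv_prop[k])

            # current log target (with transform jacobians)
            cur = loglik_i[i] + _group_logprior_i(
                xu[i], xv[i], beta_a, beta_b, beta_norm, scale
            )
            prop_ll = participant_loglik(
                model_id,
                decision_id,
                task_id,
                xu_prop,
                xv_prop,
                outcome[lo:hi],
                estimate[lo:hi],
                choice[lo:hi],
                tib[lo:hi],
                beta_scale,
            )
            prop = prop_ll + _group_logprior_i(
                xu_prop, xv_prop, beta_a, beta_b, beta_norm, scale
            )
            for k in range(n_unit):
                cur += math.log(xu[i, k] * (1.0 - xu[i, k]))
                prop += math.log(xu_prop[k] * (1.0 - xu_prop[k]))
            for k in range(n_var):
                cur += zv[i, k]
                prop += zv_prop[k]

            accepted = 0.0
            if math.log(np.random.random() + 1e-300) < prop - cur:
                zu[i] = zu_prop
                zv[i] = zv_prop
                xu[i] = xu_prop
                xv[i] = xv_prop
                loglik_i[i] = prop_ll
                accepted = 1.0
            if adapt:
                step_ind[i] *= math.exp(c_t * (accepted - 0.23))

        if adapt:
            # accumulate per-coordinate spread; refresh proposal shape
            run_count += 1
            for i in range(n_part):
                for k in range(n_unit):
                    d = zu[i, k] - run_mean[i, k]
                    run_mean[i, k] += d / run_count
                    run_m2[i, k] += d * (zu[i, k] - run_mean[i, k])
                for k in range(n_var):
                    d = zv[i, k] - run_mean[i, n_unit + k]
                    run_mean[i, n_unit + k] += d / run_count
                    run_m2[i, n_unit + k] += d * (zv[i, k] - run_mean[i, n_unit + k])
            if run_count >= 200 and run_count % 50 == 0:
                for i in range(n_part):
                    for k in range(nd):
                        sd = math.sqrt(run_m2[i, k] / (run_count - 1))
                        prop_sd[i, k] = max(sd, 0.02)

        # --- hyperparameter sweeps (cheap: no likelihood evaluations) ---
        for _sweep in range(3):
            _do_hyper_sweep(
                xu,
                xv,
                m,
                logn,
                nprec,
                logscale,
                scale,
                step_m,
                step_n,
                step_s,
                adapt,
                c_t,
            )

        if it >= burn_in and (it - burn_in) % thin == 0 and kept < n_keep:
            out_m[kept] = m
            out_n[kept] = nprec
            out_s[kept] = scale
            out_u[kept] = xu
            out_v[kept] = xv
            kept += 1

    return out_m, out_n, out_s, out_u, out_v


@njit(cache=True)
def _do_hyper_sweep(
    xu, xv, m, logn, nprec, logscale, scale, step_m, step_n, step_s, adapt, c_t
):
    n_part = xu.shape[0]
    n_unit = m.shape[0]
    n_var = scale.shape[0]
    if True:
        # --- group-mean hyperparameters (unit params) ---
        for k in range(n_unit):
            y = math.log(m[k] / (1.0 - m[k]))
            y_prop = y + step_m[k] * np.random.standard_normal()
            m_prop = _sigmoid(y_prop)
            a_cur = m[k] * nprec[k]
            b_cur = (1.0 - m[k]) * nprec[k]
            a_prop = m_prop * nprec[k]
            b_prop = (1.0 - m_prop) * nprec[k]
            cur = math.log(m[k] * (1.0 - m[k])) - n_part * _betaln(a_cur, b_cur)
            prop = math.log(m_prop * (1.0 - m_prop)) - n_part * _betaln(a_prop, b_prop)
            for i in range(n_part):
                cur += _beta_logpdf_unnorm(xu[i, k], a_cur, b_cur)
                prop += _beta_logpdf_unnorm(xu[i, k], a_prop, b_prop)
            accepted = 0.0
            if math.log(np.random.random() + 1e-300) < prop - cur:
                m[k] = m_prop
                accepted = 1.0
            if adapt:
                step_m[k] *= math.exp(c_t * (accepted - 0.44))

        # --- group-precision hyperparameters (uniform on log scale) ---
        for k in range(n_unit):
            y_prop = logn[k] + step_n[k] * np.random.standard_normal()
            accepted = 0.0
            if LOG_PREC_LO <= y_prop <= LOG_PREC_HI:
                n_prop = math.exp(y_prop)
                a_cur = m[k] * nprec[k]
                b_cur = (1.0 - m[k]) * nprec[k]
                a_prop = m[k] * n_prop
                b_prop = (1.0 - m[k]) * n_prop
                cur = -n_part * _betaln(a_cur, b_cur)
                prop = -n_part * _betaln(a_prop, b_prop)
                for i in range(n_part):
                    cur += _beta_logpdf_unnorm(xu[i, k], a_cur, b_cur)
                    prop += _beta_logpdf_unnorm(xu[i, k], a_prop, b_prop)
                if math.log(np.random.random() + 1e-300) < prop - cur:
                    logn[k] = y_prop
                    nprec[k] = n_prop
                    accepted = 1.0
            if adapt:
                step_n[k] *= math.exp(c_t * (accepted - 0.44))

        # --- half-Cauchy scale hyperparameters (uniform prior on scale) ---
        for k in range(n_var):
            y_prop = logscale[k] + step_s[k] * np.random.standard_normal()
            accepted = 0.0
            s_prop = math.exp(y_prop)
            if s_prop <= SCALE_HI:
                cur = logscale[k]  # jacobian of log transform, uniform prior
                prop = y_prop
                for i in range(n_part):
                    cur += halfcauchy_logpdf(xv[i, k], scale[k])
                    prop += halfcauchy_logpdf(xv[i, k], s_prop)
                if math.log(np.random.random() + 1e-300) < prop - cur:
                    logscale[k] = y_prop
                    scale[k] = s_prop
                    accepted = 1.0
            if adapt:
                step_s[k] *= math.exp(c_t * (accepted - 0.44))
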