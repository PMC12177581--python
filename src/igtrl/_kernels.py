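"""Jit-compiled teacher-forced negative log-likelihood kernels, one per model.

Each kernel walks a session once, updating the model's latent variables on the
participant's actual choice and outcome at every trial and accumulating
-log P(choice_t | history). They mirror the agent classes exactly (tests
assert equality against the agent route) and exist because model fitting and
recovery evaluate the likelihood tens of thousands of times per cohort.

Shared signature: ``nll(params, choices, gains, losses, w_ini, scale)`` with
``choices`` 1-based int64, ``gains``/``losses`` raw currency magnitudes,
``w_ini`` the initial exploitation weights (only the EEF kernel reads it) and
``scale`` the monetary divisor. Probabilities are floored at 1e-12 before the
log so the NLL stays finite at bound-edge parameters.
"""

from __future__ import annotations

import numpy as np
from numba import njit

P_FLOOR = 1e-12


@njit(cache=True)
def _neg_log_softmax_entry(w, d):
    """-log softmax(w)[d], max-subtracted, floored."""
    m = w[0]
    for i in range(1, 4):
        if w[i] > m:
            m = w[i]
    z = 0.0
    for i in range(4):
        z += np.exp(w[i] - m)
    p = np.exp(w[d] - m) / z
    if p < P_FLOOR:
        p = P_FLOOR
    return -np.log(p)


@njit(cache=True)
def nll_eef(params, choices, gains, losses, w_ini, scale):
    """params = (lam, theta, phi, beta, la)."""
    lam, theta, phi, beta, la = params[0], params[1], params[2], params[3], params[4]
    C = 3.0**beta - 1.0
    exploit = w_ini.copy()
    explore = np.zeros(4)
    w = np.empty(4)
    nll = 0.0
    for t in range(choices.shape[0]):
        d = choices[t] - 1
        for i in range(4):
            w[i] = (exploit[i] + explore[i]) * C
        nll += _neg_log_softmax_entry(w, d)
        g = gains[t] / scale
        l = losses[t] / scale
        v = (g**theta if g > 0.0 else 0.0) - la * (l**theta if l > 0.0 else 0.0)
        for i in range(4):
            exploit[i] *= 1.0 - lam
            explore[i] = lam * explore[i] + (1.0 - lam) * phi
        exploit[d] += v
        explore[d] = 0.0
    return nll


@njit(cache=True)
def nll_ev(params, choices, gains, losses, w_ini, scale):
    """params = (w, a, c)."""
    wgt, a, c = params[0], params[1], params[2]
    ev = np.zeros(4)
    w = np.empty(4)
    nll = 0.0
    for t in range(choices.shape[0]):
        d = choices[t] - 1
        theta = ((t + 1) / 10.0) ** c
        for i in range(4):
            w[i] = theta * ev[i]
        nll += _neg_log_softmax_entry(w, d)
        v = (1.0 - wgt) * (gains[t] / scale) - wgt * (losses[t] / scale)
        ev[d] += a * (v - ev[d])
    return nll


@njit(cache=True)
def _prospect(net, shape, la):
    if net > 0.0:
        return net**shape
    if net < 0.0:
        return -la * (-net) ** shape
    return 0.0


@njit(cache=True)
def nll_pvl(params, choices, gains, losses, w_ini, scale):
    """params = (shape, loss_aversion, decay, c)."""
    shape, la, decay, c = params[0], params[1], params[2], params[3]
    sens = 3.0**c - 1.0
    ev = np.zeros(4)
    w = np.empty(4)
    nll = 0.0
    for t in range(choices.shape[0]):
        d = choices[t] - 1
        for i in range(4):
            w[i] = sens * ev[i]
        nll += _neg_log_softmax_entry(w, d)
        u = _prospect((gains[t] - losses[t]) / scale, shape, la)
        for i in range(4):
            ev[i] *= decay
        ev[d] += u
    return nll


@njit(cache=True)
def nll_pvldelta(params, choices, gains, losses, w_ini, scale):
    """params = (shape, loss_aversion, a, c)."""
    shape, la, a, c = params[0], params[1], params[2], params[3]
    sens = 3.0**c - 1.0
    ev = np.zeros(4)
    w = np.empty(4)
    nll = 0.0
    for t in range(choices.shape[0]):
        d = choices[t] - 1
        for i in range(4):
            w[i] = sens * ev[i]
        nll += _neg_log_softmax_entry(w, d)
        u = _prospect((gains[t] - losses[t]) / scale, shape, la)
        ev[d] += a * (u - ev[d])
    return nll


@njit(cache=True)
def nll_orl(params, choices, gains, losses, w_ini, scale):
    """params = (a_rew, a_pun, k, beta_f, beta_p)."""
    a_rew, a_pun, k, beta_f, beta_p = params[0], params[1], params[2], params[3], params[4]
    ev = np.zeros(4)
    ef = np.zeros(4)
    ps = np.zeros(4)
    w = np.empty(4)
    nll = 0.0
    decay = 1.0 / (1.0 + k)
    for t in range(choices.shape[0]):
        d = choices[t] - 1
        for i in range(4):
            w[i] = ev[i] + beta_f * ef[i] + beta_p * ps[i]
        nll += _neg_log_softmax_entry(w, d)
        net = (gains[t] - losses[t]) / scale
        sgn = 1.0 if net > 0.0 else (-1.0 if net < 0.0 else 0.0)
        lr = a_rew if net >= 0.0 else a_pun
        lr_fic = a_pun if net >= 0.0 else a_rew
        ev[d] += lr * (net - ev[d])
        for j in range(4):
            if j == d:
                ef[j] += lr * (sgn - ef[j])
            else:
                ef[j] += lr_fic * (-sgn / 3.0 - ef[j])
        for j in range(4):
            ps[j] *= decay
        ps[d] = 1.0
    return nll


@njit(cache=True)
def nll_vpp(params, choices, gains, losses, w_ini, scale):
    """params = (a, shape, loss_aversion, ep_pos, ep_neg, k, w, c)."""
    a, shape, la = params[0], params[1], params[2]
    ep_pos, ep_neg, k, mix, c = params[3], params[4], params[5], params[6], params[7]
    sens = 3.0**c - 1.0
    ev = np.zeros(4)
    pers = np.zeros(4)
    w = np.empty(4)
    nll = 0.0
    for t in range(choices.shape[0]):
        d = choices[t] - 1
        for i in range(4):
            w[i] = sens * (mix * ev[i] + (1.0 - mix) * pers[i])
        nll += _neg_log_softmax_entry(w, d)
        net = (gains[t] - losses[t]) / scale
        u = _prospect(net, shape, la)
        ev[d] += a * (u - ev[d])
        for j in range(4):
            pers[j] *= k
        pers[d] += ep_pos if net >= 0.0 else ep_neg
    return nll


@njit(cache=True)
def nll_vse(params, choices, gains, losses, w_ini, scale):
    """params = (theta, decay, alpha, phi, c)."""
    theta, decay, alpha, phi, c = params[0], params[1], params[2], params[3], params[4]
    sens = 3.0**c - 1.0
    exploit = np.zeros(4)
    explore = np.zeros(4)
    w = np.empty(4)
    nll = 0.0
    for t in range(choices.shape[0]):
        d = choices[t] - 1
        for i in range(4):
            w[i] = sens * (exploit[i] + explore[i])
        nll += _neg_log_softmax_entry(w, d)
        g = gains[t] / scale
        l = losses[t] / scale
        v = (g**theta if g > 0.0 else 0.0) - (l**theta if l > 0.0 else 0.0)
        for i in range(4):
            exploit[i] *= decay
            explore[i] += alpha * (phi - explore[i])
        exploit[d] += v
        explore[d] = 0.0
    return nll
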