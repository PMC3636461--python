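"""Voltage- and calcium-dependent gating kinetics for the PG cell channel set.

Each function returns ``(x_inf, tau_x)`` for one gating variable, evaluated
elementwise on scalars or numpy arrays.  Membrane potential ``v`` is in mV,
perimembrane calcium ``ca`` in mM, and every time constant in ms.  The
temperature coefficient phi is *not* applied here: steady states are
temperature independent and phi enters only the gating state-update equation
dx/dt = phi * (x_inf - x) / tau_x.

Kinetics are pinned at 23 degC (the slice-recording temperature); the phi
values in :mod:`pgcell.channels` already encode that correction.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "vtrap",
    "na_m", "na_h", "kdr_m", "ka_m", "ka_h", "h_m",
    "cal_m", "cal_h_inf", "cat_m", "cat_h", "kca_m", "can_m",
]

#: relative argument below which x/(1 - exp(-x/k)) switches to its series
SINGULARITY_GUARD = 1e-7


def vtrap(x, k):
    """Evaluate ``x / (1 - exp(-x/k))`` with its removable singularity guarded.

    Near x = 0 the expression tends to ``k``; within a relative window of
    ``SINGULARITY_GUARD`` the two-term series ``k + x/2`` is used instead of
    the (catastrophically cancelling) direct form.  The guarded branch is an
    explicit analytic limit, not a voltage perturbation, so results are
    deterministic and continuous across the switch.
    """
    x = np.asarray(x, dtype=float)
    u = x / k
    small = np.abs(u) < SINGULARITY_GUARD
    # avoid overflow warnings in the dead branch
    safe_u = np.where(small, 1.0, u)
    direct = np.where(small, 0.0, x / (1.0 - np.exp(-safe_u)))
    series = k + 0.5 * x
    out = np.where(small, series, direct)
    return out if out.ndim else float(out)


def _alpha_beta(alpha, beta):
    s = alpha + beta
    return alpha / s, 1.0 / s


# --- fast sodium -----------------------------------------------------------

def na_m(v):
    """Na activation: alpha/beta form, order 3."""
    alpha = 0.32 * vtrap(np.asarray(v, float) + 39.0, 4.0)
    beta = 0.28 * vtrap(-(np.asarray(v, float) + 12.0), 5.0)
    return _alpha_beta(alpha, beta)


def na_h(v):
    """Na inactivation: alpha/beta form, order 1."""
    v = np.asarray(v, float)
    alpha = 0.128 * np.exp(-(v + 35.0) / 18.0)
    beta = 4.0 / (1.0 + np.exp(-(v + 12.0) / 5.0))
    return _alpha_beta(alpha, beta)


# --- delayed-rectifier potassium ------------------------------------------

def kdr_m(v):
    """Delayed-rectifier K activation: alpha/beta form, order 4."""
    v = np.asarray(v, float)
    alpha = 0.032 * vtrap(v + 37.0, 5.0)
    beta = 0.5 * np.exp(-(v + 42.0) / 40.0)
    return _alpha_beta(alpha, beta)


# --- A-type potassium -------------------------------------------------------

def ka_m(v):
    """A-type K activation; tau_m = 50 * beta / (1 + alpha) ms."""
    v = np.asarray(v, float)
    alpha = np.exp(-0.118 * (v + 33.6))
    beta = np.exp(-0.071 * (v + 33.6))
    return 1.0 / (1.0 + alpha), 50.0 * beta / (1.0 + alpha)


def ka_h(v):
    """A-type K inactivation; tau_h = 12.5 * beta / (1 + alpha) ms."""
    v = np.asarray(v, float)
    alpha = np.exp(0.157 * (v + 83.0))
    beta = np.exp(0.157 * (v + 83.0))
    return 1.0 / (1.0 + alpha), 12.5 * beta / (1.0 + alpha)


# --- hyperpolarization-activated cation current (H) -------------------------

def h_m(v):
    """H-current activation (PG-cell derived kinetics)."""
    v = np.asarray(v, float)
    inf = 1.0 / (1.0 + np.exp((v + 80.0) / 10.0))
    tau = 1176.5 * np.exp((v + 65.0) / 23.5) / (1.0 + np.exp((v + 65.0) / 11.8))
    return inf, tau


# --- L-type calcium ---------------------------------------------------------

def cal_m(v):
    """L-type Ca activation; fixed tau_m = 20 ms."""
    v = np.asarray(v, float)
    inf = 1.0 / (1.0 + np.exp(-(v + 30.0) / 6.0))
    return inf, np.full_like(inf, 20.0) if inf.ndim else 20.0


def cal_h_inf(ca):
    """L-type Ca inactivation, instantaneous calcium block: 1.245/(1.245+ca)."""
    ca = np.asarray(ca, float)
    out = 1.245 / (1.245 + ca)
    return out if out.ndim else float(out)


# --- T-type calcium ---------------------------------------------------------

def cat_m(v):
    """T-type Ca activation (low-threshold)."""
    v = np.asarray(v, float)
    inf = 1.0 / (1.0 + np.exp(-(v + 49.0) / 7.4))
    tau = 3.0 + 1.0 / (np.exp((v + 24.0) / 10.0) + np.exp(-(v + 99.0) / 15.0))
    return inf, tau


def cat_h(v):
    """T-type Ca inactivation; deinactivates at hyperpolarized potentials."""
    v = np.asarray(v, float)
    inf = 1.0 / (1.0 + np.exp((v + 77.0) / 5.0))
    tau = 85.0 + 1.0 / (np.exp((v + 45.0) / 4.0) + np.exp(-(v + 404.0) / 50.0))
    return inf, tau


# --- calcium-gated currents -------------------------------------------------

def kca_m(ca):
    """K(Ca) activation from perimembrane [Ca] (mM); half-saturation ca^2 = 6.25e-4."""
    ca = np.asarray(ca, float)
    ca2 = ca * ca
    inf = ca2 / (6.25e-4 + ca2)
    tau = np.maximum(0.021 / (6.25e-4 + ca2), 0.1)
    return inf, tau


def can_m(ca):
    """CAN activation from perimembrane [Ca] (mM); half-saturation ca^2 = 1e-4."""
    ca = np.asarray(ca, float)
    ca2 = ca * ca
    inf = ca2 / (1e-4 + ca2)
    tau = np.maximum(1.0 / (2e-3 + 20.0 * ca2), 0.1)
    return inf, tau
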