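"""One-dimensional effective theory of three coupled excitable junctions.

A central junction of length l1 is flanked by two mirror-symmetric outer
junctions of length l2 between fixed walls, so l1 + 2*l2 = 3*L at all
times.  Each junction carries a linear spring (constant k, natural length
L, the 1D stand-in for cell elasticity), a constant line tension
(Lambda1 for the center, Lambda2 for the outer pair), and a binary active
element contributing tension Gamma*l while active.  The effective
Hamiltonian is

    H_eff = (k/2)(l1 - L)^2 + k (l2 - L)^2 + Lambda1 l1 + 2 Lambda2 l2
            + (Gamma1/2) l1^2 + Gamma2 l2^2.

Dynamics are the overdamped gradient flow of H_eff on the single degree
of freedom left by the wall constraint,

    mu * dl2/dt = -dH_eff/dl2  with  l1 = 3L - 2*l2,

i.e. dl2/dt = (2/mu) * (T1 - T2) with per-junction tensions
T_i = k(l_i - L) + Lambda_i + Gamma_i l_i.  This reduction is what makes
the closed-form propagation threshold exact: with the center activated at
t = 0 and kL = 0 the outer strain is
eps2(t) = [Gamma0/(3+2*Gamma0)] * (1 - exp(-2*(3+2*Gamma0) t)), whose
eps_on-crossing time is tau_p below.

Junction rest lengths remodel at rate kL exactly as in the 2D model and
enter only through the strain that drives the three-state automaton; the
springs always reference the natural length L.

Nondimensional defaults: k = L = mu = 1, Gamma0 = 1, eps_on = 0.1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .tissue_geometry import ACTIVE, INACTIVE, REFRACTORY

__all__ = [
    "EffParams", "EffOutcome", "eff_equilibrium", "simulate_effective",
    "tau_p", "reactivation_coefficients", "reactivation_range",
    "eps_on_reactivation_window", "effective_phase_diagram",
    "critical_tau_propagation", "critical_tau_reactivation",
]

NO_PROPAGATION = "no_propagation"
PULSE = "pulse"
REACTIVATION = "reactivation"


@dataclass
class EffParams:
    """Constants of the three-junction model (nondimensional defaults)."""

    k: float = 1.0
    L: float = 1.0
    mu: float = 1.0
    lam1: float = 0.1
    lam2: float = 0.1
    gamma0: float = 1.0
    eps_on: float = 0.1
    k_l: float = 0.0
    tau_act: float = 0.1
    tau_ref: float = 0.1
    dt: float = 1e-3

    def __post_init__(self) -> None:
        for name in ("k", "L", "mu", "gamma0", "tau_act", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.eps_on < 0 or self.k_l < 0 or self.tau_ref < 0:
            raise ValueError("eps_on, k_l and tau_ref must be non-negative")


@dataclass
class EffOutcome:
    """Trajectories and classification of one effective-model run.

    label is one of "no_propagation" (outer junctions never activate),
    "pulse" (outer junctions activate, center never re-activates) or
    "reactivation" (the center re-activates when its refractory period
    ends).
    """

    label: str
    times: np.ndarray
    l1: np.ndarray
    l2: np.ndarray
    l01: np.ndarray
    l02: np.ndarray
    eps1: np.ndarray
    eps2: np.ndarray
    state1: np.ndarray
    state2: np.ndarray
    outer_activation_time: float | None = None
    center_reactivation_time: float | None = None


def eff_equilibrium(params: EffParams) -> tuple[float, float]:
    """Passive equilibrium lengths (l1, l2) under the wall constraint.

    Tension balance k(l1 - L) + Lambda1 = k(l2 - L) + Lambda2 with
    l1 + 2*l2 = 3*L gives l1 = L + 2(Lambda2 - Lambda1)/(3k).  A higher
    outer tension (Lambda2 > Lambda1) leaves a long central junction
    flanked by two short ones, and vice versa.
    """
    l1 = params.L + 2.0 * (params.lam2 - params.lam1) / (3.0 * params.k)
    l2 = 0.5 * (3.0 * params.L - l1)
    return l1, l2


def simulate_effective(params: EffParams, tau: float | None = None,
                       k_l: float | None = None,
                       record: bool = False) -> EffOutcome:
    """Integrate the three-junction model from equilibrium, center active.

    ``tau`` (if given) sets tau_act = tau_ref = tau and ``k_l`` overrides
    the remodeling rate, matching the usual (tau, kL) phase-space scan.
    The run covers t in [0, tau_act + tau_ref] plus a few steps so that
    the center's refractory period can end and its re-activation (strain
    still at or above eps_on at that instant) can be registered.
    """
    p = params
    if tau is not None or k_l is not None:
        p = replace(p, **({"tau_act": tau, "tau_ref": tau} if tau is not None else {}),
                    **({"k_l": k_l} if k_l is not None else {}))
    dt = p.dt
    l1, l2 = eff_equilibrium(p)
    l01, l02 = l1, l2
    state1, t1m = ACTIVE, p.tau_act     # center manually activated at t=0
    state2, t2m = INACTIVE, 0.0         # the two outer junctions (mirror pair)

    horizon = p.tau_act + p.tau_ref + 5 * dt
    n_steps = int(math.ceil(horizon / dt))
    outer_on_t = None
    center_re_t = None

    traj = {k: [] for k in ("t", "l1", "l2", "l01", "l02", "e1", "e2", "s1", "s2")}

    def log(t, e1, e2):
        traj["t"].append(t)
        traj["l1"].append(l1)
        traj["l2"].append(l2)
        traj["l01"].append(l01)
        traj["l02"].append(l02)
        traj["e1"].append(e1)
        traj["e2"].append(e2)
        traj["s1"].append(state1)
        traj["s2"].append(state2)

    if record:
        log(0.0, 0.0, 0.0)

    for n in range(1, n_steps + 1):
        g1 = p.gamma0 if state1 == ACTIVE else 0.0
        g2 = p.gamma0 if state2 == ACTIVE else 0.0
        t1 = p.k * (l1 - p.L) + p.lam1 + g1 * l1
        t2 = p.k * (l2 - p.L) + p.lam2 + g2 * l2
        l2 = l2 + dt * (2.0 / p.mu) * (t1 - t2)
        l1 = 3.0 * p.L - 2.0 * l2
        if not (math.isfinite(l1) and math.isfinite(l2)):
            raise FloatingPointError("effective-model state diverged; reduce dt")
        if p.k_l > 0:
            l01 += -dt * p.k_l * (l01 - l1)
            l02 += -dt * p.k_l * (l02 - l2)
        e1 = (l1 - l01) / l01
        e2 = (l2 - l02) / l02

        # automaton, simultaneous transitions from pre-step states
        if state1 != INACTIVE:
            t1m -= dt
        if state2 != INACTIVE:
            t2m -= dt
        new1, new2 = state1, state2
        if state1 == ACTIVE and t1m <= 1e-12:
            new1, t1m = REFRACTORY, p.tau_ref
        elif state1 == REFRACTORY and t1m <= 1e-12:
            new1, t1m = INACTIVE, 0.0
        elif state1 == INACTIVE and e1 >= p.eps_on:
            new1, t1m = ACTIVE, p.tau_act
        if state2 == ACTIVE and t2m <= 1e-12:
            new2, t2m = REFRACTORY, p.tau_ref
        elif state2 == REFRACTORY and t2m <= 1e-12:
            new2, t2m = INACTIVE, 0.0
        elif state2 == INACTIVE and e2 >= p.eps_on:
            new2, t2m = ACTIVE, p.tau_act
        if state2 == INACTIVE and new2 == ACTIVE and outer_on_t is None:
            outer_on_t = n * dt
        # the center started active, so any INACTIVE -> ACTIVE transition
        # is a re-activation (its refractory period has just ended)
        if state1 == INACTIVE and new1 == ACTIVE and center_re_t is None:
            center_re_t = n * dt
        state1, state2 = new1, new2
        if record:
            log(n * dt, e1, e2)

    if outer_on_t is None:
        label = NO_PROPAGATION
    elif center_re_t is not None:
        label = REACTIVATION
    else:
        label = PULSE
    arr = {k: np.array(v) for k, v in traj.items()}
    return EffOutcome(label=label, times=arr["t"], l1=arr["l1"], l2=arr["l2"],
                      l01=arr["l01"], l02=arr["l02"], eps1=arr["e1"],
                      eps2=arr["e2"], state1=arr["s1"], state2=arr["s2"],
                      outer_activation_time=outer_on_t,
                      center_reactivation_time=center_re_t)


# ---------------------------------------------------------------------- #
# closed-form criteria (kL = 0, symmetric tensions, k = L = mu = 1)


def tau_p(gamma0: float, eps_on: float) -> float:
    """Minimum activation period for propagation at kL = 0.

    The outer-junction strain under a centrally active junction is
    eps2(t) = [g/(3+2g)] (1 - exp(-2(3+2g) t)); tau_p is its eps_on
    crossing.  Returns 0 for eps_on = 0 (activity always propagates) and
    +inf when eps_on >= g/(3+2g) (the strain saturates below threshold,
    so no activation period suffices).
    """
    if gamma0 <= 0 or eps_on < 0:
        raise ValueError("gamma0 must be positive and eps_on non-negative")
    if eps_on == 0.0:
        return 0.0
    arg = gamma0 - (3.0 + 2.0 * gamma0) * eps_on
    if arg <= 0.0:
        return math.inf
    return math.log(gamma0 / arg) / (2.0 * (3.0 + 2.0 * gamma0))


def reactivation_coefficients(gamma0: float, eps_on: float) -> tuple[float, float]:
    """Coefficients (A, B) of the central-junction reactivation inequality.

    With tp = tau_p(gamma0, eps_on),

        A = [2g/(3+g)]  (1 - exp(-2(3+g)  tp)) exp(6 tp),
        B = [2g/(3+2g)] (1 - exp(-2(3+2g) tp)) exp(2(3+2g) tp),

    and the center re-activates when its refractory period ends iff
    A exp(-6 tau) - B exp(-6 (2+g) tau) - eps_on > 0.  At eps_on = 0,
    tp = 0 and A = B = 0: reactivation never occurs, only pulses.
    """
    tp = tau_p(gamma0, eps_on)
    if math.isinf(tp):
        raise ValueError("no propagation at these parameters "
                         "(tau_p is infinite); coefficients undefined")
    g = gamma0
    a = (2.0 * g / (3.0 + g)) * (1.0 - math.exp(-2.0 * (3.0 + g) * tp)) \
        * math.exp(6.0 * tp)
    b = (2.0 * g / (3.0 + 2.0 * g)) * (1.0 - math.exp(-2.0 * (3.0 + 2.0 * g) * tp)) \
        * math.exp(2.0 * (3.0 + 2.0 * g) * tp)
    return a, b


def _window_lhs(gamma0, eps_on):
    """LHS of the reactivation inequality as a function of y = exp(-6 tau)."""
    a, b = reactivation_coefficients(gamma0, eps_on)

    def lhs(y):
        return a * y - b * y ** (2.0 + gamma0) - eps_on

    return lhs


def reactivation_range(gamma0: float, eps_on: float):
    """Activation-period interval (tau1, tau2) with central re-activation.

    Solves A exp(-6 tau) - B exp(-6(2+g) tau) > eps_on for tau > tau_p; in
    y = exp(-6 tau) the left side is A y - B y^(2+g) (a cubic for g = 1).
    Returns None when the inequality has no solution (quiescent-or-pulse
    only), which for g = 1 happens outside 0.077 < eps_on < 0.2.
    """
    from scipy.optimize import brentq

    tp = tau_p(gamma0, eps_on)
    if math.isinf(tp):
        return None
    if eps_on == 0.0:
        return None  # A = B = 0: pure pulse regime
    lhs = _window_lhs(gamma0, eps_on)
    y_p = math.exp(-6.0 * tp)
    ys = np.linspace(1e-9, y_p * (1.0 - 1e-12), 4000)
    vals = lhs(ys)
    pos = vals > 0.0
    if not np.any(pos):
        return None
    first, last = np.flatnonzero(pos)[[0, -1]]
    # bracket the two sign changes (or clamp at the tau_p end)
    y_hi = y_p if last == len(ys) - 1 else brentq(lhs, ys[last], ys[last + 1],
                                                  xtol=1e-14)
    y_lo = brentq(lhs, ys[first - 1], ys[first], xtol=1e-14) if first > 0 else ys[0]
    tau1 = -math.log(y_hi) / 6.0
    tau2 = -math.log(y_lo) / 6.0
    return (tau1, tau2)


def eps_on_reactivation_window(gamma0: float = 1.0,
                               tol: float = 1e-5) -> tuple[float, float]:
    """Endpoints of the eps_on interval with a nonempty reactivation window.

    The upper endpoint is the propagation-validity boundary
    eps_on = g/(3+2g) (tau_p diverges there); the lower endpoint is found
    by bisecting the predicate "reactivation_range is nonempty", which
    switches once on (0, upper).
    """
    upper = gamma0 / (3.0 + 2.0 * gamma0)

    def nonempty(e):
        return reactivation_range(gamma0, e) is not None

    if not nonempty(upper * (1.0 - 1e-6)):
        raise RuntimeError("reactivation window empty even at the upper "
                           "validity boundary; nothing to bracket")
    lo, hi = 1e-6, upper * (1.0 - 1e-6)
    if nonempty(lo):
        return lo, upper
    while hi - lo > tol:
        midp = 0.5 * (lo + hi)
        if nonempty(midp):
            hi = midp
        else:
            lo = midp
    return 0.5 * (lo + hi), upper


# ---------------------------------------------------------------------- #
# numeric phase boundaries and phase diagram


def critical_tau_propagation(params: EffParams, k_l: float,
                             tau_max: float = 5.0, tol: float = 1e-4):
    """Smallest activation period with outer activation, by bisection.

    Propagation is monotone in tau (the outer strain crossing happens at a
    fixed time as long as the center is still active), so a single
    bisection applies.  Returns None if even tau_max does not propagate.
    """
    if simulate_effective(params, tau=tau_max, k_l=k_l).label != NO_PROPAGATION:
        hi = tau_max
    else:
        return None
    lo = params.dt
    if simulate_effective(params, tau=lo, k_l=k_l).label != NO_PROPAGATION:
        return lo
    while hi - lo > tol:
        midp = 0.5 * (lo + hi)
        if simulate_effective(params, tau=midp, k_l=k_l).label != NO_PROPAGATION:
            hi = midp
        else:
            lo = midp
    return 0.5 * (lo + hi)


def critical_tau_reactivation(params: EffParams, k_l: float,
                              tau_max: float = 5.0, scan_step: float = 2e-3,
                              scan_span: float = 0.5, tol: float = 1e-4):
    """Smallest activation period with central re-activation.

    Scans tau upward from the propagation threshold (the reactivation band
    sits a small gap above it; at kL = 0 the whole band is below
    tau_p + 0.1 for the default parameters), then bisects the onset.
    Returns None if no reactivation occurs within ``scan_span`` above the
    propagation threshold.
    """
    tp = critical_tau_propagation(params, k_l, tau_max=tau_max, tol=tol)
    if tp is None:
        return None
    tau = tp
    found = None
    while tau <= min(tau_max, tp + scan_span):
        if simulate_effective(params, tau=tau, k_l=k_l).label == REACTIVATION:
            found = tau
            break
        tau += scan_step
    if found is None:
        return None
    lo, hi = max(tp, found - scan_step), found
    while hi - lo > tol:
        midp = 0.5 * (lo + hi)
        if simulate_effective(params, tau=midp, k_l=k_l).label == REACTIVATION:
            hi = midp
        else:
            lo = midp
    return 0.5 * (lo + hi)


def effective_phase_diagram(params: EffParams, tau_grid: Sequence[float],
                            kl_grid: Sequence[float]):
    """Outcome label for each (tau, kL) grid point, as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for kl in kl_grid:
        for tau in tau_grid:
            out = simulate_effective(params, tau=float(tau), k_l=float(kl))
            rows.append({"tau": float(tau), "kL": float(kl), "label": out.label})
    return pd.DataFrame(rows)
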