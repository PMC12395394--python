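"""Measurement and classification of tissue activity patterns.

The three tissue-level outcomes are distinguished from the active-junction
fraction time series of a run seeded with a local activation:

* quiescent -- the maximum active fraction over the run never exceeds the
  propagation threshold theta_prop (the seeded activity dies out locally),
* pulse     -- activity propagates but dies: the final active fraction
  (mean over the last 10% of the horizon, robust to oscillation phase)
  is zero,
* wave      -- self-sustained activity: the final active fraction stays
  positive.

theta_prop = 0.1 is used for both ordered and disordered tissues.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from . import excitability, mechanics
from .excitability import ExcitParams, seed_activation
from .simulation import SimulationResult, run_simulation
from .tissue_geometry import ACTIVE, INACTIVE, REFRACTORY, Tissue

__all__ = ["OutcomeRecord", "state_fractions", "total_strain",
           "classify_outcome", "record_from_result", "run_and_classify",
           "sweep_phase_diagram", "critical_kl", "measure_wavelength",
           "radial_activity_profile"]

QUIESCENT = "quiescent"
PULSE = "pulse"
WAVE = "wave"

#: maximum-active-fraction threshold separating propagation from quiescence
THETA_PROP = 0.1
#: fraction of the run horizon averaged to define the "final" state
FINAL_WINDOW = 0.1


def state_fractions(tissue: Tissue) -> tuple[float, float, float]:
    """(inactive, active, refractory) junction fractions; they sum to 1."""
    n = tissue.n_junctions
    return (np.count_nonzero(tissue.state == INACTIVE) / n,
            np.count_nonzero(tissue.state == ACTIVE) / n,
            np.count_nonzero(tissue.state == REFRACTORY) / n)


def total_strain(tissue: Tissue) -> float:
    """Sum of junction strains over the tissue."""
    return float(np.sum(excitability.junction_strains(tissue)))


@dataclass
class OutcomeRecord:
    """Summary of one seeded run: time series plus classification."""

    times: np.ndarray
    f_inactive: np.ndarray
    f_active: np.ndarray
    f_refractory: np.ndarray
    total_strain: np.ndarray
    max_active_fraction: float
    final_active_fraction: float
    final_inactive_fraction: float
    label: str


def classify_outcome(record: OutcomeRecord,
                     theta_prop: float = THETA_PROP) -> str:
    """quiescent / pulse / wave from the active-fraction summary."""
    if record.max_active_fraction <= theta_prop:
        return QUIESCENT
    return WAVE if record.final_active_fraction > 0 else PULSE


def record_from_result(result: SimulationResult,
                       theta_prop: float = THETA_PROP) -> OutcomeRecord:
    t = result.times
    tail = t >= t[-1] - FINAL_WINDOW * (t[-1] - t[0])
    rec = OutcomeRecord(
        times=t, f_inactive=result.f_inactive, f_active=result.f_active,
        f_refractory=result.f_refractory, total_strain=result.total_strain,
        max_active_fraction=float(result.f_active.max()),
        final_active_fraction=float(result.f_active[tail].mean()),
        final_inactive_fraction=float(result.f_inactive[tail].mean()),
        label="")
    rec.label = classify_outcome(rec, theta_prop)
    return rec


def run_and_classify(tissue: Tissue, mech: mechanics.MechParams,
                     excit: ExcitParams, t_end: float | None = None,
                     theta_prop: float = THETA_PROP,
                     **run_kwargs) -> OutcomeRecord:
    """Seeded-run convenience wrapper: integrate, summarize, classify."""
    result = run_simulation(tissue, mech, excit, t_end=t_end, **run_kwargs)
    return record_from_result(result, theta_prop)


def sweep_phase_diagram(tissue_factory: Callable[[], Tissue],
                        tau_grid: Sequence[float], kl_grid: Sequence[float],
                        mech: mechanics.MechParams,
                        eps_on: float = 0.1, gamma0: float | None = None,
                        seed_junction: int | None = None,
                        t_end: float = 20.0, theta_prop: float = THETA_PROP):
    """Classify every (tau, kL) grid point with the same seeded junction.

    The factory is called once; each grid point restarts from a fresh copy
    of that equilibrated tissue with the same single junction activated.
    Failed runs are recorded with label "failed" and the sweep continues.
    Returns a DataFrame (tau, kL, max_active_fraction,
    final_active_fraction, label).
    """
    import dataclasses

    import pandas as pd

    base = tissue_factory()
    g0 = mech.gamma0 if gamma0 is None else gamma0
    rows = []
    for kl in kl_grid:
        for tau in tau_grid:
            m = dataclasses.replace(mech, k_l=float(kl))
            e = ExcitParams(eps_on=eps_on, tau_act=float(tau),
                            tau_ref=float(tau), gamma0=g0)
            t = base.copy()
            seed_activation(t, "single", e, junction=seed_junction)
            try:
                rec = run_and_classify(t, m, e, t_end=t_end,
                                       theta_prop=theta_prop, copy=False)
                rows.append({"tau": float(tau), "kL": float(kl),
                             "max_active_fraction": rec.max_active_fraction,
                             "final_active_fraction": rec.final_active_fraction,
                             "label": rec.label})
            except FloatingPointError as err:  # pragma: no cover - diagnostic path
                rows.append({"tau": float(tau), "kL": float(kl),
                             "max_active_fraction": np.nan,
                             "final_active_fraction": np.nan,
                             "label": f"failed: {err}"})
    return pd.DataFrame(rows)


def critical_kl(tissue: Tissue, seed_junction: int, tau: float,
                mech: mechanics.MechParams, eps_on: float = 0.1,
                kl_max: float = 2.0, n_bisect: int = 6,
                t_end: float = 20.0, theta_prop: float = THETA_PROP):
    """Critical remodeling rate above which the seeded activity cannot spread.

    Bisects kL on the boundary where the run's maximum active fraction
    crosses ``theta_prop`` (same definition as the quiescence boundary of
    the phase diagram).  Deterministic given (tissue, junction).  Returns
    None if there is no propagation even at kL = 0.
    """
    import dataclasses

    def propagates(kl: float) -> bool:
        m = dataclasses.replace(mech, k_l=kl)
        e = ExcitParams(eps_on=eps_on, tau_act=tau, tau_ref=tau,
                        gamma0=mech.gamma0)
        t = tissue.copy()
        seed_activation(t, "single", e, junction=seed_junction)
        rec = run_and_classify(t, m, e, t_end=t_end, theta_prop=theta_prop,
                               copy=False)
        return rec.max_active_fraction > theta_prop

    if not propagates(0.0):
        return None
    if propagates(kl_max):
        return kl_max
    lo, hi = 0.0, kl_max
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        if propagates(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------- #
# wavelength of a radially propagating wave pattern


def radial_activity_profile(tissue: Tissue, origin: np.ndarray,
                            bin_width: float):
    """Active-junction fraction vs minimum-image distance from ``origin``."""
    mid = tissue.edge_midpoints()
    d = tissue.box.minimum_image(mid - np.asarray(origin))
    r = np.hypot(d[:, 0], d[:, 1])
    r_max = 0.5 * min(tissue.box.lx, tissue.box.ly)
    n_bins = max(2, int(r_max / bin_width))
    edges_r = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    total, _ = np.histogram(r, bins=edges_r)
    active, _ = np.histogram(r[tissue.state == ACTIVE], bins=edges_r)
    with np.errstate(invalid="ignore"):
        frac = np.where(total > 0, active / np.maximum(total, 1), 0.0)
    centers = 0.5 * (edges_r[:-1] + edges_r[1:])
    return centers, frac


def measure_wavelength(snapshots: Sequence[tuple[float, Tissue]] | Sequence[Tissue],
                       origin: np.ndarray, bin_width: float,
                       min_rings: int = 2):
    """Mean spacing of concentric activity rings around ``origin``.

    For each snapshot the radial activity profile is binned with
    ``bin_width`` (one hexagon edge length is the natural choice) and its
    local maxima located; the wavelength is the mean spacing between
    consecutive maxima, averaged over the snapshots that show at least
    ``min_rings`` rings.  Returns None (undefined) when fewer than two
    rings are ever detected -- e.g. for pulse or quiescent runs.
    """
    from scipy.signal import find_peaks

    spacings = []
    for snap in snapshots:
        tissue = snap[1] if isinstance(snap, tuple) else snap
        centers, frac = radial_activity_profile(tissue, origin, bin_width)
        if frac.max() <= 0:
            continue
        peaks, _ = find_peaks(frac, height=0.3 * frac.max(), distance=2)
        if len(peaks) >= min_rings:
            spacings.extend(np.diff(centers[peaks]))
    if not spacings:
        return None
    return float(np.mean(spacings))
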