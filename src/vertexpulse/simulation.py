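"""Time-stepping driver coupling mechanics and junction excitability.

Per-step operation order (fixed; documented in docs/methods.md):

1. compute net vertex forces,
2. forward-Euler update of vertex positions (re-reduced into the box),
3. forward-Euler update of junction rest lengths,
4-5. junction automaton update (timers, active->refractory->inactive,
   strain-triggered activation) from the post-move geometry,
6. T1 checks on the post-move junction lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import excitability, mechanics
from .tissue_geometry import ACTIVE, INACTIVE, REFRACTORY, Tissue

__all__ = ["SimulationResult", "run_simulation"]


@dataclass
class SimulationResult:
    """Sampled time series of a tissue simulation."""

    times: np.ndarray
    f_inactive: np.ndarray
    f_active: np.ndarray
    f_refractory: np.ndarray
    total_strain: np.ndarray
    n_t1_events: int
    snapshots: list = field(default_factory=list)  # (time, Tissue) pairs
    final_tissue: Tissue | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "time": self.times,
            "f_inactive": self.f_inactive,
            "f_active": self.f_active,
            "f_refractory": self.f_refractory,
            "total_strain": self.total_strain,
        })


def _sample(tissue: Tissue):
    n = tissue.n_junctions
    f_i = np.count_nonzero(tissue.state == INACTIVE) / n
    f_a = np.count_nonzero(tissue.state == ACTIVE) / n
    f_r = np.count_nonzero(tissue.state == REFRACTORY) / n
    strain = float(np.sum(excitability.junction_strains(tissue)))
    return f_i, f_a, f_r, strain


def run_simulation(tissue: Tissue, mech: mechanics.MechParams,
                   excit: excitability.ExcitParams, t_end: float | None = None,
                   record_interval: float = 0.1,
                   snapshot_interval: float | None = None,
                   copy: bool = True) -> SimulationResult:
    """Integrate the excitable tissue from its current state to ``t_end``.

    Samples junction-state fractions and the total junction strain every
    ``record_interval`` time units (including t = 0 and the final time);
    if ``snapshot_interval`` is set, deep tissue copies are stored at that
    cadence for post-hoc analysis.  With ``copy=True`` (default) the input
    tissue is left untouched.
    """
    if t_end is None:
        t_end = mech.t_end
    if copy:
        tissue = tissue.copy()
    dt = mech.dt
    n_steps = int(round(t_end / dt))
    rec_every = max(1, int(round(record_interval / dt)))
    snap_every = (None if snapshot_interval is None
                  else max(1, int(round(snapshot_interval / dt))))

    times, fi, fa, fr, strain = [], [], [], [], []
    snapshots = []
    n_t1 = 0

    def record(t):
        a, b, c, s = _sample(tissue)
        times.append(t)
        fi.append(a)
        fa.append(b)
        fr.append(c)
        strain.append(s)

    record(0.0)
    if snap_every is not None:
        snapshots.append((0.0, tissue.copy()))

    for n in range(1, n_steps + 1):
        mechanics.step(tissue, mech)
        excitability.update_states(tissue, excit, dt)
        n_t1 += len(mechanics.t1_transitions(tissue, mech))
        if n % rec_every == 0 or n == n_steps:
            record(n * dt)
        if snap_every is not None and (n % snap_every == 0 or n == n_steps):
            snapshots.append((n * dt, tissue.copy()))

    return SimulationResult(
        times=np.array(times), f_inactive=np.array(fi), f_active=np.array(fa),
        f_refractory=np.array(fr), total_strain=np.array(strain),
        n_t1_events=n_t1, snapshots=snapshots, final_tissue=tissue)
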