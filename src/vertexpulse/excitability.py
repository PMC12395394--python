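"""Three-state junction automaton and activation seeding.

Each cell junction is a mechanically excitable unit in one of three states:

* inactive   -- no contractility; becomes active when its strain
                eps = (l - l0)/l0 reaches the threshold eps_on,
* active     -- contractility Gamma0 for a duration tau_act (turnover of
                the active machinery), then refractory,
* refractory -- no contractility and cannot re-activate for a duration
                tau_ref (coarse-grained contractility inhibitors), then
                inactive again.

The threshold comparison is inclusive (eps >= eps_on), timers are
decremented by dt and fire when they reach zero (durations are quantized
to multiples of dt), and all transitions within a step are computed from
the pre-step states and applied simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tissue_geometry import ACTIVE, INACTIVE, REFRACTORY, Tissue

__all__ = ["ExcitParams", "junction_strain", "junction_strains",
           "update_states", "seed_activation"]

_TIMER_EPS = 1e-9  # float tolerance when testing a decremented timer against 0


@dataclass
class ExcitParams:
    """Excitability constants.

    eps_on  : activation strain threshold (dimensionless)
    tau_act : active-state duration (units t0)
    tau_ref : refractory duration (units t0)
    gamma0  : contractility while active (units K*A0)
    """

    eps_on: float = 0.1
    tau_act: float = 1.0
    tau_ref: float = 1.0
    gamma0: float = 0.5

    def __post_init__(self) -> None:
        if self.eps_on < 0 or self.tau_ref < 0:
            raise ValueError("eps_on and tau_ref must be non-negative")
        if self.tau_act <= 0 or self.gamma0 <= 0:
            raise ValueError("tau_act and gamma0 must be strictly positive")

    @property
    def delta(self) -> float:
        """Refractory-to-active duration ratio, tau_ref / tau_act."""
        return self.tau_ref / self.tau_act


def junction_strains(tissue: Tissue) -> np.ndarray:
    """Strain eps = (l - l0)/l0 for every junction."""
    if np.any(tissue.rest_length <= 0):
        raise ValueError("junction rest lengths must be positive")
    return (tissue.edge_lengths() - tissue.rest_length) / tissue.rest_length


def junction_strain(tissue: Tissue, junction: int) -> float:
    return float(junction_strains(tissue)[junction])


def update_states(tissue: Tissue, params: ExcitParams, dt: float) -> Tissue:
    """Advance the junction automaton by one time step (in place).

    From the pre-step states, simultaneously: active junctions whose timer
    has run out turn refractory; refractory junctions whose timer has run
    out turn inactive (they may activate on a *later* step); inactive
    junctions at or above the strain threshold turn active.
    """
    state = tissue.state
    timed = state != INACTIVE
    tissue.timer[timed] -= dt

    expired = tissue.timer <= _TIMER_EPS
    to_refractory = (state == ACTIVE) & expired
    to_inactive = (state == REFRACTORY) & expired
    to_active = (state == INACTIVE) & (junction_strains(tissue) >= params.eps_on)

    state[to_refractory] = REFRACTORY
    tissue.timer[to_refractory] = params.tau_ref
    state[to_inactive] = INACTIVE
    tissue.timer[to_inactive] = 0.0
    state[to_active] = ACTIVE
    tissue.timer[to_active] = params.tau_act
    tissue.gamma = np.where(state == ACTIVE, params.gamma0, 0.0)
    return tissue


# ---------------------------------------------------------------------- #
# initial-condition builders


def _central_junction(tissue: Tissue) -> int:
    mid = tissue.edge_midpoints()
    center = 0.5 * tissue.box.dims
    d = tissue.box.minimum_image(mid - center)
    return int(np.argmin(np.einsum("ij,ij->i", d, d)))


def _row_junctions(tissue: Tissue, n_row: int) -> np.ndarray:
    """Indices of ``n_row`` collinear junctions forming a line near the center.

    Junctions are grouped by orientation and offset; the most populous
    collinear family closest to the box center is used and the ``n_row``
    members nearest the center along the line are returned.
    """
    dvec = tissue.edge_vectors()
    ln = np.linalg.norm(dvec, axis=1)
    # the straightest families in a hexagonal tiling are the vertical edges;
    # pick the orientation class with the smallest |dx|/l spread around 0
    vertical = np.abs(dvec[:, 0]) / ln < 1e-6
    if not np.any(vertical):
        raise ValueError("tissue has no axis-aligned junction family for row "
                         "seeding; pass explicit junction indices instead")
    mid = tissue.edge_midpoints()
    xs = mid[vertical, 0]
    x0 = xs[np.argmin(np.abs(xs - 0.5 * tissue.box.lx))]
    line = np.flatnonzero(vertical & (np.abs(mid[:, 0] - x0) < 1e-6))
    if len(line) < n_row:
        raise ValueError(f"only {len(line)} collinear junctions available, "
                         f"requested {n_row}")
    dy = np.abs(tissue.box.minimum_image(mid[line] - 0.5 * tissue.box.dims)[:, 1])
    return line[np.argsort(dy)][:n_row]


def seed_activation(tissue: Tissue, mode: str, params: ExcitParams,
                    junction: int | None = None, n_row: int = 8,
                    side: str = "left",
                    junctions: np.ndarray | None = None) -> Tissue:
    """Impose the initial activation pattern on an equilibrated tissue.

    mode "single"              : one junction active (given index, or the
                                 junction nearest the box center);
    mode "row"                 : a contiguous set of collinear junctions
                                 active (explicit ``junctions`` or ``n_row``
                                 auto-selected near the center);
    mode "row_plus_refractory" : the row active plus the adjacent junction
                                 layer on ``side`` ("left"/"right" of the
                                 line) refractory with a full tau_ref timer
                                 -- the spiral-pair initial condition.

    Activated junctions receive a full tau_act timer.
    """
    if np.any(tissue.state != INACTIVE):
        raise ValueError("seed_activation expects an all-inactive tissue")

    if mode == "single":
        j = _central_junction(tissue) if junction is None else int(junction)
        if not 0 <= j < tissue.n_junctions:
            raise ValueError(f"junction index {j} out of range")
        active = np.array([j])
    elif mode in ("row", "row_plus_refractory"):
        if junctions is not None:
            active = np.asarray(junctions, dtype=np.int64)
            if active.size == 0 or active.min() < 0 or active.max() >= tissue.n_junctions:
                raise ValueError("row selector names nonexistent junctions")
        else:
            active = _row_junctions(tissue, n_row)
    else:
        raise ValueError(f"unknown seeding mode {mode!r}")

    tissue.state[active] = ACTIVE
    tissue.timer[active] = params.tau_act
    tissue.gamma[active] = params.gamma0

    if mode == "row_plus_refractory":
        if side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        mid = tissue.edge_midpoints()
        x_line = float(np.mean(mid[active, 0]))
        row_vertices = np.unique(tissue.edges[active])
        touches = np.isin(tissue.edges[:, 0], row_vertices) | \
            np.isin(tissue.edges[:, 1], row_vertices)
        dx = tissue.box.minimum_image(mid - np.array([x_line, 0.0]))[:, 0]
        on_side = dx < 0 if side == "left" else dx > 0
        layer = np.flatnonzero(touches & on_side & (tissue.state == INACTIVE))
        tissue.state[layer] = REFRACTORY
        tissue.timer[layer] = params.tau_ref
    return tissue
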