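"""Forces, overdamped dynamics, rest-length remodeling, and T1 transitions.

The tissue energy is

    H = (K/2) * sum_cells (A - A0)^2  +  Lambda * sum_junctions l,

an area-elastic term plus an interfacial tension term.  Junction
contractility enters as a force, not an energy: an active junction with
contractility Gamma pulls its endpoints together with a length-dependent
tension Gamma * l, i.e. the active force on vertex i from junction (i, j)
is -Gamma * (r_i - r_j) (minimum image).  Vertices follow overdamped
first-order dynamics mu * dr/dt = -dH/dr + F_act integrated with forward
Euler, and every junction's rest length relaxes toward its current length
at rate kL (viscous strain relaxation), dl0/dt = -kL * (l0 - l).

Units: K = A0 = 1 and mu = 0.636 make the simulation time unit
t0 = mu / (0.636 * K * sqrt(A0)) equal to 1; forces are in K * A0^(3/2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tissue_geometry import INACTIVE, Tissue, validate_tissue

__all__ = ["MechParams", "total_energy", "net_vertex_forces", "step",
           "t1_transitions", "equilibrate"]


@dataclass
class MechParams:
    """Mechanical constants of the vertex model (defaults: standard set).

    k_area : area elastic modulus K (units K)
    a0     : preferred cell area A0
    lam    : junction line tension Lambda (units K*A0^(3/2))
    mu     : vertex friction coefficient (units K*t0); 0.636 makes t0 = 1
    gamma0 : contractility of an active junction (units K*A0)
    k_l    : rest-length remodeling rate kL (units 1/t0)
    l_t1   : junction length threshold for a T1 exchange (units sqrt(A0))
    dt     : forward-Euler time step (units t0)
    t_end  : default simulation horizon (units t0)
    """

    k_area: float = 1.0
    a0: float = 1.0
    lam: float = 0.1
    mu: float = 0.636
    gamma0: float = 0.5
    k_l: float = 1.0
    l_t1: float = 0.01
    dt: float = 0.01
    t_end: float = 20.0

    def __post_init__(self) -> None:
        for name in ("k_area", "a0", "mu", "gamma0", "l_t1", "dt", "t_end"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.lam < 0 or self.k_l < 0:
            raise ValueError("lam and k_l must be non-negative")


def total_energy(tissue: Tissue, params: MechParams) -> float:
    """Tissue Hamiltonian: area elasticity plus interfacial tension."""
    areas = tissue.cell_areas()
    elastic = 0.5 * params.k_area * np.sum((areas - params.a0) ** 2)
    interfacial = params.lam * tissue.edge_lengths().sum()
    return float(elastic + interfacial)


def net_vertex_forces(tissue: Tissue, params: MechParams) -> np.ndarray:
    """Per-vertex 2D force: -dH/dr plus the active junction contractions.

    The active force of junction (i, j) on vertex i is -Gamma_ij*(r_i - r_j),
    so the two endpoint contributions are equal and opposite and the total
    force over the tissue vanishes identically (momentum-free dynamics).
    """
    top = tissue.topology
    n_v = tissue.n_vertices
    forces = np.zeros((n_v, 2))

    # area elasticity: F_i = -K (A_c - A0) dA_c/dr_i per incident cell,
    # with dA/dx_i = (y_next - y_prev)/2, dA/dy_i = (x_prev - x_next)/2
    areas = tissue.cell_areas()
    pressure = -params.k_area * (areas - params.a0)
    d = tissue.slot_deltas()
    chord = d + d[top.slot_prev]          # r_next - r_prev per slot
    g = 0.5 * np.column_stack([chord[:, 1], -chord[:, 0]])
    w = pressure[top.slot_cell]
    fx = np.bincount(top.slot_vertex, weights=w * g[:, 0], minlength=n_v)
    fy = np.bincount(top.slot_vertex, weights=w * g[:, 1], minlength=n_v)
    forces[:, 0] += fx
    forces[:, 1] += fy

    # line tension + active contraction: both pull endpoints together
    dvec = tissue.edge_vectors()          # r_j - r_i per junction (i, j)
    ln = np.linalg.norm(dvec, axis=1)
    coef = params.lam / ln + tissue.gamma
    fe = coef[:, None] * dvec
    i, j = tissue.edges[:, 0], tissue.edges[:, 1]
    forces[:, 0] += np.bincount(i, weights=fe[:, 0], minlength=n_v)
    forces[:, 1] += np.bincount(i, weights=fe[:, 1], minlength=n_v)
    forces[:, 0] -= np.bincount(j, weights=fe[:, 0], minlength=n_v)
    forces[:, 1] -= np.bincount(j, weights=fe[:, 1], minlength=n_v)
    return forces


def step(tissue: Tissue, params: MechParams) -> Tissue:
    """Advance positions and rest lengths by one forward-Euler step.

    Positions update first (r += dt/mu * F, re-reduced into the box); rest
    lengths then relax toward the post-move junction lengths.  Junction
    state changes and T1 checks are separate operations, applied after this
    one in the standard per-step order (see `vertexpulse.simulation`).
    The tissue is modified in place and returned.
    """
    forces = net_vertex_forces(tissue, params)
    if not np.all(np.isfinite(forces)):
        raise FloatingPointError("non-finite force encountered; reduce dt")
    tissue.positions = tissue.box.wrap(
        tissue.positions + (params.dt / params.mu) * forces)
    if params.k_l > 0:
        ln = tissue.edge_lengths()
        tissue.rest_length += -params.dt * params.k_l * (tissue.rest_length - ln)
    return tissue


# ---------------------------------------------------------------------- #
# T1 transitions


def t1_transitions(tissue: Tissue, params: MechParams):
    """Resolve every junction shorter than l_t1 by a neighbor exchange.

    A short junction (a, b) collapses to a (transient) 4-fold vertex that
    is immediately re-opened transverse to the old junction: the new
    junction keeps the two vertices, is placed along the perpendicular
    bisector of the old one with length and rest length 1.5*l_t1, and is
    reset to the inactive, non-contractile state.  The two cells that
    shared the old junction each lose one side, the two cells at its
    endpoints each gain one; V, E and C are unchanged.

    Swaps that would create a 2-sided cell are skipped.  Returns the list
    of junction indices swapped.
    """
    swapped = []
    skipped: set = set()
    while True:
        lengths = tissue.edge_lengths()
        short = np.flatnonzero(lengths < params.l_t1)
        short = [e for e in short if e not in skipped and e not in swapped]
        if not short:
            break
        e_idx = int(min(short, key=lambda e: lengths[e]))
        if _t1_swap(tissue, e_idx, params):
            swapped.append(e_idx)
        else:
            skipped.add(e_idx)
    return swapped


def _t1_swap(tissue: Tissue, e_idx: int, params: MechParams) -> bool:
    a, b = (int(v) for v in tissue.edges[e_idx])
    cells_a = [ci for ci, loop in enumerate(tissue.cells) if a in loop]
    cells_b = [ci for ci, loop in enumerate(tissue.cells) if b in loop]

    def _succ(loop, v):
        k = int(np.flatnonzero(loop == v)[0])
        return int(loop[(k + 1) % len(loop)])

    p_cell = q_cell = None
    for ci in cells_a:
        if ci in cells_b:
            loop = tissue.cells[ci]
            if _succ(loop, a) == b:
                p_cell = ci      # traverses a -> b; keeps a
            elif _succ(loop, b) == a:
                q_cell = ci      # traverses b -> a; keeps b
    if p_cell is None or q_cell is None:
        return False
    r_cell = next((ci for ci in cells_a if ci not in (p_cell, q_cell)), None)
    s_cell = next((ci for ci in cells_b if ci not in (p_cell, q_cell)), None)
    if r_cell is None or s_cell is None or r_cell == s_cell:
        return False
    if len(tissue.cells[p_cell]) <= 3 or len(tissue.cells[q_cell]) <= 3:
        return False  # would create a 2-sided cell

    # rewired edges: (a, v) with v = successor of a in Q becomes (b, v);
    #                (b, w) with w = successor of b in P becomes (a, w)
    v_n = _succ(tissue.cells[q_cell], a)
    w_n = _succ(tissue.cells[p_cell], b)
    lookup = {frozenset(map(int, e)): k for k, e in enumerate(tissue.edges)}
    e_av = lookup.get(frozenset((a, v_n)))
    e_bw = lookup.get(frozenset((b, w_n)))
    if e_av is None or e_bw is None:
        return False

    # geometry: re-open perpendicular to the old junction at its midpoint,
    # with vertex a displaced toward cell P (the cell that keeps it)
    dvec = tissue.box.minimum_image(tissue.positions[b] - tissue.positions[a])
    ln = float(np.linalg.norm(dvec))
    mid = tissue.positions[a] + 0.5 * dvec
    if ln == 0.0:
        normal = np.array([1.0, 0.0])
    else:
        normal = np.array([-dvec[1], dvec[0]]) / ln
    l_new = 1.5 * params.l_t1
    tissue.positions[a] = tissue.box.wrap(mid + 0.5 * l_new * normal)
    tissue.positions[b] = tissue.box.wrap(mid - 0.5 * l_new * normal)

    def _drop(loop, vv):
        return loop[loop != vv]

    def _insert_before(loop, anchor, vv):
        k = int(np.flatnonzero(loop == anchor)[0])
        return np.insert(loop, k, vv)

    tissue.cells[p_cell] = _drop(tissue.cells[p_cell], b)
    tissue.cells[q_cell] = _drop(tissue.cells[q_cell], a)
    tissue.cells[r_cell] = _insert_before(tissue.cells[r_cell], a, b)
    tissue.cells[s_cell] = _insert_before(tissue.cells[s_cell], b, a)

    tissue.edges[e_av] = (b, v_n) if tissue.edges[e_av][0] == a else (v_n, b)
    tissue.edges[e_bw] = (a, w_n) if tissue.edges[e_bw][0] == b else (w_n, a)

    tissue.rest_length[e_idx] = l_new
    tissue.gamma[e_idx] = 0.0
    tissue.state[e_idx] = INACTIVE
    tissue.timer[e_idx] = 0.0
    tissue.invalidate_topology()
    return True


# ---------------------------------------------------------------------- #
# equilibration


def equilibrate(tissue: Tissue, params: MechParams, tol: float = 1e-6,
                method: str = "lbfgs", max_rounds: int = 50,
                max_euler_steps: int = 2_000_000) -> Tissue:
    """Relax the tissue (all contractilities zero) to mechanical equilibrium.

    Drives the passive energy downhill until the largest vertex force is
    below ``tol``, resolving T1 exchanges between relaxation rounds, then
    zeroes all strains (l0 = l) and resets every junction to the inactive
    state.  ``method="lbfgs"`` (default) uses quasi-Newton minimization of
    the Hamiltonian -- equivalent stationary points to the overdamped
    dynamics, deterministic, and much faster; ``method="euler"`` steps the
    dynamics directly.
    """
    if np.any(tissue.gamma != 0):
        raise ValueError("equilibrate requires all contractilities to be zero")
    if method == "lbfgs":
        _equilibrate_lbfgs(tissue, params, tol, max_rounds)
    elif method == "euler":
        _equilibrate_euler(tissue, params, tol, max_euler_steps)
    else:
        raise ValueError(f"unknown method {method!r}")

    resid = np.abs(net_vertex_forces(tissue, params)).max()
    if resid >= tol:
        raise RuntimeError(f"equilibration did not converge: max |force| = {resid:.3e}")
    tissue.rest_length = tissue.edge_lengths().copy()
    tissue.gamma[:] = 0.0
    tissue.state[:] = INACTIVE
    tissue.timer[:] = 0.0
    return tissue


def _equilibrate_lbfgs(tissue, params, tol, max_rounds):
    from scipy.optimize import minimize

    shape = tissue.positions.shape

    def fun(x):
        tissue.positions = x.reshape(shape)
        e = total_energy(tissue, params)
        g = -net_vertex_forces(tissue, params)
        return e, g.ravel()

    for _ in range(max_rounds):
        res = minimize(fun, tissue.positions.ravel(), jac=True,
                       method="L-BFGS-B",
                       options={"maxiter": 20000, "ftol": 1e-18, "gtol": 0.1 * tol})
        tissue.positions = tissue.box.wrap(res.x.reshape(shape))
        swapped = t1_transitions(tissue, params)
        resid = np.abs(net_vertex_forces(tissue, params)).max()
        if not swapped and resid < tol:
            return
    # fall through: final residual checked by caller


def _equilibrate_euler(tissue, params, tol, max_steps):
    check_every = 50
    for n in range(max_steps):
        forces = net_vertex_forces(tissue, params)
        if n % check_every == 0 and np.abs(forces).max() < tol:
            return
        tissue.positions = tissue.box.wrap(
            tissue.positions + (params.dt / params.mu) * forces)
        t1_transitions(tissue, params)
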