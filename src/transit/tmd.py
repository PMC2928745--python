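"""Targeted molecular dynamics: biasing potential, schedule, run orchestration.

The biasing potential is the standard targeted-MD harmonic penalty on the
best-fit RMSD between the current and target coordinates of the targeted
atom subset, where k is the total applied force constant, N the number of
targeted atoms, and RMSD*(t) the scheduled value decreasing linearly from
the initial RMSD to the final target (0 for a complete transition).  Forces
are the exact gradient of the potential and act on targeted atoms only; the
rest of the system evolves freely under the coarse-grained engine.

Two published normalisations of the same penalty are in circulation and
both are supported:

* ``"per-atom"`` (default, the convention of the reference MD engine's TMD
  module): U = (k/2N) * Σ-form, i.e. U = (k/2)(RMSD − RMSD*)² with forces
  F_i = −(k/N)(1 − RMSD*/RMSD)(x_i − x̂_i).  Each targeted atom effectively
  carries a spring of stiffness k/N — the "effective per-atom force
  constant" (1 kcal/mol/Å² in the canonical run configurations).
* ``"rms"``: the formula read literally on the RMS-normalised coordinate,
  U = (k/2N)(RMSD − RMSD*)², whose gradient is N-fold weaker per atom.

Runs use the per-atom convention: it is the one under which the canonical
total force constants (k = N) produce the printed per-atom stiffness and
drive the transition.

A biased run is preceded (optionally) by short screening runs over candidate
helix subsets and followed by free relaxation; :func:`screen_subsets` ranks
subsets by an opening score built from pore-radius changes in the
intracellular vs extracellular lumen halves, flagging subsets that open the
extracellular side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cg_model import ENM, DynamicsParams, enm_energy_forces, langevin_step
from .errors import DynamicsError, TransitError
from .geometry import best_fit_rmsd, rmsd_gradient
from .structio import Selection, Structure, Trajectory, select

__all__ = ["TMDParams", "TMDState", "schedule_value", "tmd_energy_forces",
           "effective_per_atom_k", "run_biased", "run_free", "screen_subsets"]


@dataclass
class TMDParams:
    """Parameters of the biasing potential.

    ``k_total`` is the total force constant k (kcal/mol/Å²); the targeted
    selection defines N; ``rmsd_final`` is the scheduled endpoint (0 for a
    full transition).
    """

    k_total: float
    targeted: Selection
    n_steps: int
    rmsd_final: float = 0.0
    #: Normalisation of the penalty: "per-atom" (reference-engine
    #: convention; per-atom stiffness k/N) or "rms" (literal RMS formula).
    convention: str = "per-atom"
    #: Sustained-lag warning: RMSD - RMSD* above this (Å) ...
    lag_threshold: float = 2.0
    #: ... for more than this fraction of the run triggers "bias too weak".
    lag_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.k_total <= 0:
            raise ValueError("k_total must be positive")
        if len(self.targeted) < 3:
            raise ValueError("need at least 3 targeted atoms")
        if self.rmsd_final < 0:
            raise ValueError("rmsd_final must be non-negative")
        if self.n_steps < 1:
            raise ValueError("n_steps must be positive")
        if self.convention not in ("per-atom", "rms"):
            raise ValueError("convention must be 'per-atom' or 'rms'")


@dataclass
class TMDState:
    """Per-step state of a biased run."""

    step: int
    rmsd_t: float
    rmsd_star: float
    bias_energy: float
    forces: np.ndarray | None = None


def schedule_value(step: int, n_steps: int, rmsd_initial: float,
                   rmsd_final: float) -> float:
    """Linearly scheduled target RMSD* at a given step."""
    if not 0 <= step <= n_steps:
        raise ValueError(f"step {step} outside [0, {n_steps}]")
    return rmsd_initial + (step / n_steps) * (rmsd_final - rmsd_initial)


def effective_per_atom_k(params: TMDParams) -> float:
    """k_total / N: the effective force constant per targeted atom."""
    return params.k_total / len(params.targeted)


def _bias_on_points(current: np.ndarray, target: np.ndarray, k_total: float,
                    rmsd_star: float,
                    convention: str = "per-atom") -> tuple[float, np.ndarray, float]:
    """Bias energy and forces on the targeted points themselves.

    The returned forces are the exact gradient of the returned energy in
    either convention; the two differ only by the N-fold normalisation of
    the spring stiffness (see module docstring).
    """
    n = current.shape[0]
    grad, at_target = rmsd_gradient(current, target)
    if at_target:
        rmsd_t = 0.0
    else:
        rmsd_t = best_fit_rmsd(current, target)
    lag = rmsd_t - rmsd_star
    k_eff = k_total if convention == "per-atom" else k_total / n
    energy = 0.5 * k_eff * lag ** 2
    forces = -k_eff * lag * grad
    return energy, forces, rmsd_t


def tmd_energy_forces(coords: np.ndarray, target_coords: np.ndarray,
                      params: TMDParams, rmsd_star: float,
                      convention: str | None = None
                      ) -> tuple[float, np.ndarray, float]:
    """Bias energy and per-atom forces over the full structure.

    Forces are exactly zero on non-targeted atoms.  ``convention``
    overrides ``params.convention`` ("rms" evaluates the literal
    U = (k/2N)(RMSD − RMSD*)² with its gradient).  Returns
    ``(bias_energy, forces, rmsd_t)``.
    """
    coords = np.asarray(coords, dtype=float)
    target_coords = np.asarray(target_coords, dtype=float)
    if coords.shape != target_coords.shape:
        raise ValueError("current and target coordinate shapes differ")
    idx = params.targeted.indices
    energy, f_t, rmsd_t = _bias_on_points(
        coords[idx], target_coords[idx], params.k_total, rmsd_star,
        convention or params.convention)
    forces = np.zeros_like(coords)
    forces[idx] = f_t
    return energy, forces, rmsd_t


# ---------------------------------------------------------------------------
# Run orchestration
# ---------------------------------------------------------------------------

def _node_maps(structure: Structure, enm: ENM) -> tuple[np.ndarray, np.ndarray]:
    """Map every atom to the ENM node it rides on.

    Returns ``(node_atom_indices, atom_to_node)`` where non-node atoms are
    assigned the node of their own residue (they are convected rigidly with
    their Cα during dynamics).
    """
    node_idx = enm.node_selection.indices
    node_of_residue: dict[tuple[str, int], int] = {}
    for local, ai in enumerate(node_idx):
        atom = structure.atoms[ai]
        node_of_residue[(atom.chain, atom.resid)] = local
    atom_to_node = np.full(structure.n_atoms, -1, dtype=np.intp)
    for ai, atom in enumerate(structure.atoms):
        local = node_of_residue.get((atom.chain, atom.resid))
        if local is not None:
            atom_to_node[ai] = local
    return node_idx, atom_to_node


def _full_frame(base_coords: np.ndarray, node_idx: np.ndarray,
                atom_to_node: np.ndarray, node_start: np.ndarray,
                node_now: np.ndarray) -> np.ndarray:
    """Full-atom frame: every atom displaced with its residue's node."""
    disp = node_now - node_start
    frame = base_coords.copy()
    riding = atom_to_node >= 0
    frame[riding] += disp[atom_to_node[riding]]
    return frame


def _targeted_node_locals(structure: Structure, enm: ENM,
                          targeted: Selection) -> np.ndarray:
    node_idx = enm.node_selection.indices
    pos = {int(a): l for l, a in enumerate(node_idx)}
    locals_ = []
    for ai in targeted.indices:
        if int(ai) not in pos:
            atom = structure.atoms[ai]
            raise TransitError(
                f"targeted atom {atom.chain}:{atom.resid}:{atom.name} is not "
                f"an ENM node; target Cα atoms only")
        locals_.append(pos[int(ai)])
    return np.asarray(locals_, dtype=np.intp)


def run_biased(structure: Structure, target: Structure, enm: ENM,
               tmd_params: TMDParams, dyn_params: DynamicsParams,
               report_every: int = 100) -> tuple[Trajectory, pd.DataFrame]:
    """Targeted-MD run: ENM forces plus the scheduled RMSD bias.

    The schedule interpolates RMSD* linearly from the initial targeted-atom
    RMSD to ``tmd_params.rmsd_final`` over ``n_steps``.  Returns the
    trajectory (frames every ``report_every`` steps, plus the final state)
    and a per-step log with columns step, rmsd_t, rmsd_star, bias_energy.
    Deterministic for a given seed.
    """
    if structure.n_atoms != target.n_atoms:
        raise TransitError("structure and target atom counts differ")
    node_idx, atom_to_node = _node_maps(structure, enm)
    t_local = _targeted_node_locals(structure, enm, tmd_params.targeted)
    base = structure.coords
    x = base[node_idx].copy()
    target_t = target.coords[tmd_params.targeted.indices]
    rng = np.random.default_rng(dyn_params.seed)
    n_steps = tmd_params.n_steps
    rmsd0 = best_fit_rmsd(x[t_local], target_t)
    frames = [base.copy()]
    times = [0.0]
    log = {"step": [], "rmsd_t": [], "rmsd_star": [], "bias_energy": []}
    lag_run = 0
    warned = False
    for step in range(n_steps):
        rmsd_star = schedule_value(step, n_steps, rmsd0, tmd_params.rmsd_final)
        _, f_enm = enm_energy_forces(enm, x)
        u, f_bias, rmsd_t = _bias_on_points(x[t_local], target_t,
                                            tmd_params.k_total, rmsd_star,
                                            tmd_params.convention)
        forces = f_enm
        forces[t_local] += f_bias
        log["step"].append(step)
        log["rmsd_t"].append(rmsd_t)
        log["rmsd_star"].append(rmsd_star)
        log["bias_energy"].append(u)
        if rmsd_t - rmsd_star > tmd_params.lag_threshold:
            lag_run += 1
            if not warned and lag_run > tmd_params.lag_fraction * n_steps:
                warnings.warn(
                    f"bias too weak: RMSD lags RMSD* by more than "
                    f"{tmd_params.lag_threshold} Å for over "
                    f"{tmd_params.lag_fraction:.0%} of the run")
                warned = True
        else:
            lag_run = 0
        try:
            x = langevin_step(x, forces, dyn_params, rng, step_index=step)
        except DynamicsError:
            raise
        if (step + 1) % report_every == 0 or step + 1 == n_steps:
            frames.append(_full_frame(base, node_idx, atom_to_node,
                                      base[node_idx], x))
            times.append((step + 1) * dyn_params.dt)
    # Closing log entry at the schedule endpoint.
    rmsd_end = best_fit_rmsd(x[t_local], target_t)
    star_end = schedule_value(n_steps, n_steps, rmsd0, tmd_params.rmsd_final)
    log["step"].append(n_steps)
    log["rmsd_t"].append(rmsd_end)
    log["rmsd_star"].append(star_end)
    k_eff = tmd_params.k_total if tmd_params.convention == "per-atom" \
        else tmd_params.k_total / len(t_local)
    log["bias_energy"].append(0.5 * k_eff * (rmsd_end - star_end) ** 2)
    traj = Trajectory(np.stack(frames), np.array(times),
                      template=structure.copy())
    return traj, pd.DataFrame(log)


def run_free(structure: Structure, enm: ENM, dyn_params: DynamicsParams,
             n_steps: int, report_every: int = 100) -> Trajectory:
    """Unbiased dynamics: post-TMD relaxation or control run."""
    if n_steps < 1:
        raise ValueError("n_steps must be positive")
    node_idx, atom_to_node = _node_maps(structure, enm)
    base = structure.coords
    x = base[node_idx].copy()
    rng = np.random.default_rng(dyn_params.seed)
    frames = [base.copy()]
    times = [0.0]
    for step in range(n_steps):
        _, forces = enm_energy_forces(enm, x)
        x = langevin_step(x, forces, dyn_params, rng, step_index=step)
        if (step + 1) % report_every == 0 or step + 1 == n_steps:
            frames.append(_full_frame(base, node_idx, atom_to_node,
                                      base[node_idx], x))
            times.append((step + 1) * dyn_params.dt)
    return Trajectory(np.stack(frames), np.array(times),
                      template=structure.copy())


def quench_frame(structure: Structure, enm: ENM,
                 hold: Selection | None = None, k_hold: float = 5.0,
                 max_steps: int = 500) -> Structure:
    """Quenched snapshot: network minimisation of a (thermal) frame.

    Removes thermal jitter before single-frame structural analyses (e.g.
    contact maps), the coarse-grained analogue of analysing a relaxed final
    model rather than an instantaneous frame.  Nodes in ``hold`` (typically
    the driven atoms) are restrained at their current positions so the
    conformational state of interest is not annealed away; all other nodes
    relax freely to the nearest network minimum.
    """
    from .cg_model import minimize as enm_minimize

    node_idx, atom_to_node = _node_maps(structure, enm)
    coords = structure.coords
    x0 = coords[node_idx]
    k_r = np.zeros(len(node_idx))
    if hold is not None:
        pos = {int(a): l for l, a in enumerate(node_idx)}
        for ai in hold.indices:
            if int(ai) in pos:
                k_r[pos[int(ai)]] = k_hold
    x = enm_minimize(enm, x0, max_steps=max_steps,
                     restraint_centers=x0, restraint_k=k_r)
    return structure.with_coords(
        _full_frame(coords, node_idx, atom_to_node, x0, x))


# ---------------------------------------------------------------------------
# Pre-TMD subset screening
# ---------------------------------------------------------------------------

def screen_subsets(structure: Structure, target: Structure,
                   subset_configs: list[list[str]], enm: ENM,
                   dyn_params: DynamicsParams, n_steps: int = 2000,
                   k_per_atom: float = 1.0, report_every: int = 500,
                   z_range: tuple[float, float] = (-15.0, 15.0),
                   dz: float = 1.0, pore_seed: int = 0,
                   ec_open_threshold: float = 0.2) -> list[dict]:
    """Short biased runs over candidate helix subsets, ranked by IC opening.

    For each subset a short targeted run is performed; the opening score is
    the change in mean pore radius of the IC half minus that of the EC half
    between the first and last frames.  Subsets whose EC half widens beyond
    ``ec_open_threshold`` are flagged (unwanted extracellular opening).
    Results are sorted by descending opening score.
    """
    from .analysis import pore_profile  # local import to avoid a cycle

    if not subset_configs:
        raise TransitError("subset_configs must name at least one subset")
    results = []
    mid = 0.5 * (z_range[0] + z_range[1])
    for labels in subset_configs:
        query = "name CA and segment " + ",".join(labels)
        targeted = select(structure, query)
        params = TMDParams(k_total=k_per_atom * len(targeted),
                           targeted=targeted, n_steps=n_steps)
        traj, log = run_biased(structure, target, enm, params, dyn_params,
                               report_every=report_every)
        prof_first = pore_profile(traj.frame_structure(0), z_range, dz,
                                  optimizer_seed=pore_seed)
        prof_last = pore_profile(traj.frame_structure(traj.n_frames - 1),
                                 z_range, dz, optimizer_seed=pore_seed)
        d_ic = prof_last.mean_radius(z_range[0], mid) \
            - prof_first.mean_radius(z_range[0], mid)
        d_ec = prof_last.mean_radius(mid, z_range[1]) \
            - prof_first.mean_radius(mid, z_range[1])
        results.append({
            "labels": tuple(labels),
            "opening_score": d_ic - d_ec,
            "delta_ic_radius": d_ic,
            "delta_ec_radius": d_ec,
            "ec_opening_flag": d_ec > ec_open_threshold,
            "final_rmsd": float(log["rmsd_t"].iloc[-1]),
        })
    results.sort(key=lambda r: r["opening_score"], reverse=True)
    return results
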