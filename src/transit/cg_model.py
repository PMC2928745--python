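"""Elastic-network model (ENM) and overdamped Langevin dynamics.

This is the desk-scale stand-in for an all-atom force field: Cα nodes
connected by harmonic springs at their build-time distances, evolved by an
overdamped (Brownian) Euler–Maruyama integrator.  Non-targeted regions of a
biased run evolve under this engine alone, so they respond freely to the
motion of the driven atoms.

Two network constructions are provided:

* :func:`build_enm` — the classical anisotropic-network construction: one
  spring per Cα pair within the cutoff, rest length equal to the build-time
  distance.  Appropriate for dynamics around a single conformational basin.
* :func:`build_transition_enm` — a transition-capable network for runs
  between two conformations.  A single-basin network renders any
  large-amplitude transition strain-prohibitive, which real transporters
  are not: contacts that the transition breaks are not permanent springs.
  Springs whose length changes by more than ``rest_tol`` between the two
  endpoint conformations are therefore dropped; the retained strain keeps
  the starting state metastable while leaving the transition affordable.

Units: Å, kcal/mol, fs, K, amu.  The Brownian update is

    x += (dt / (m γ)) F + sqrt(2 kB T dt / (m γ)) ξ,   ξ ~ N(0, 1)

which is bitwise reproducible for a given seed and satisfies
fluctuation–dissipation exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize as _scipy_minimize
from scipy.spatial import cKDTree

from .constants import KB, KCAL_PER_MOL_TO_AKMA
from .errors import DynamicsError
from .structio import Selection, Structure, select

__all__ = ["ENM", "DynamicsParams", "build_enm", "build_transition_enm",
           "enm_energy_forces", "langevin_step", "minimize"]


@dataclass
class ENM:
    """Harmonic network over Cα nodes.

    ``pairs`` holds each spring once with i < j (indices into the node
    list, i.e. into ``node_selection``); rest lengths are build-time
    distances.
    """

    node_selection: Selection
    pairs: np.ndarray
    rest_lengths: np.ndarray
    spring_k: float
    cutoff: float

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=np.intp).reshape(-1, 2)
        self.rest_lengths = np.asarray(self.rest_lengths, dtype=float)
        if len(self.pairs) != len(self.rest_lengths):
            raise ValueError("pairs and rest_lengths lengths differ")
        if np.any(self.pairs[:, 0] >= self.pairs[:, 1]):
            raise ValueError("springs must be stored once with i < j")

    @property
    def n_nodes(self) -> int:
        return len(self.node_selection)

    @property
    def n_springs(self) -> int:
        return len(self.pairs)


@dataclass
class DynamicsParams:
    """Langevin/Brownian dynamics parameters.

    Temperature and friction default to the simulation conditions of the
    protocol this engine stands in for (310 K, damping 0.5 ps⁻¹); the bead
    mass is an average residue mass.  dt of 5 fs is a coarse-grained choice:
    stability requires dt/(mγ) × (max node stiffness) ≲ 1.
    """

    dt: float = 5.0            # fs
    temperature: float = 310.0  # K
    friction: float = 0.5       # ps^-1
    seed: int = 0
    bead_mass: float = 110.0    # amu

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")
        if self.friction <= 0 or self.bead_mass <= 0:
            raise ValueError("friction and bead_mass must be positive")

    @property
    def mobility(self) -> float:
        """Displacement per unit force per step, Å/(kcal/mol/Å)."""
        gamma_fs = self.friction * 1e-3
        return self.dt * KCAL_PER_MOL_TO_AKMA / (self.bead_mass * gamma_fs)

    @property
    def noise_sigma(self) -> float:
        """Per-coordinate Gaussian step width, Å."""
        return float(np.sqrt(2.0 * KB * self.temperature * self.mobility))


def _warn_isolated(structure: Structure, node_indices: np.ndarray,
                   pairs: np.ndarray) -> None:
    connected = np.zeros(len(node_indices), dtype=bool)
    if len(pairs):
        connected[pairs.ravel()] = True
    for local in np.flatnonzero(~connected):
        atom = structure.atoms[node_indices[local]]
        warnings.warn(
            f"ENM node for residue {atom.chain}:{atom.resid} has no springs "
            f"(isolated at cutoff)", stacklevel=3)


def build_enm(structure: Structure, cutoff: float = 10.0,
              spring_k: float = 1.0, node_query: str = "name CA") -> ENM:
    """Single-conformation ENM: springs between all Cα pairs within cutoff."""
    nodes = select(structure, node_query)
    if len(nodes) < 4:
        raise ValueError("need at least 4 ENM nodes")
    coords = structure.coords[nodes.indices]
    tree = cKDTree(coords)
    pairs = np.array(sorted(tree.query_pairs(cutoff)), dtype=np.intp).reshape(-1, 2)
    rest = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1) \
        if len(pairs) else np.zeros(0)
    _warn_isolated(structure, nodes.indices, pairs)
    return ENM(node_selection=nodes, pairs=pairs, rest_lengths=rest,
               spring_k=spring_k, cutoff=cutoff)


def build_transition_enm(structure_a: Structure, structure_b: Structure,
                         cutoff: float = 10.0, spring_k: float = 1.0,
                         rest_tol: float = 1.0,
                         node_query: str = "name CA") -> ENM:
    """Transition-capable ENM between two conformations.

    Candidate springs are pairs within the cutoff in conformation A (the
    build conformation, which sets the rest lengths).  Springs whose length
    changes by more than ``rest_tol`` between A and B — contacts the
    transition breaks or forms — are dropped.  The moderate retained strain
    keeps A metastable (the unbiased run stays put) while the biased run
    can afford the A→B transition.
    """
    nodes_a = select(structure_a, node_query)
    nodes_b = select(structure_b, node_query)
    if len(nodes_a) != len(nodes_b):
        raise ValueError("conformations have different node counts")
    if len(nodes_a) < 4:
        raise ValueError("need at least 4 ENM nodes")
    ca = structure_a.coords[nodes_a.indices]
    cb = structure_b.coords[nodes_b.indices]
    tree = cKDTree(ca)
    raw = np.array(sorted(tree.query_pairs(cutoff)), dtype=np.intp).reshape(-1, 2)
    da = np.linalg.norm(ca[raw[:, 0]] - ca[raw[:, 1]], axis=1)
    db = np.linalg.norm(cb[raw[:, 0]] - cb[raw[:, 1]], axis=1)
    keep = np.abs(da - db) <= rest_tol
    pairs = raw[keep]
    _warn_isolated(structure_a, nodes_a.indices, pairs)
    return ENM(node_selection=nodes_a, pairs=pairs, rest_lengths=da[keep],
               spring_k=spring_k, cutoff=cutoff)


def enm_energy_forces(enm: ENM, coords: np.ndarray) -> tuple[float, np.ndarray]:
    """Energy (kcal/mol) and per-node forces (kcal/mol/Å) of the network.

    E = Σ (k/2)(d_ij − rest_ij)²; forces are −∇E.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (enm.n_nodes, 3):
        raise ValueError(
            f"expected coords of shape ({enm.n_nodes}, 3), got {coords.shape}")
    forces = np.zeros_like(coords)
    if enm.n_springs == 0:
        return 0.0, forces
    i, j = enm.pairs[:, 0], enm.pairs[:, 1]
    dvec = coords[i] - coords[j]
    d = np.linalg.norm(dvec, axis=1)
    stretch = d - enm.rest_lengths
    energy = 0.5 * enm.spring_k * float(np.sum(stretch ** 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(d[:, None] > 1e-12, dvec / d[:, None], 0.0)
    f_pair = -enm.spring_k * stretch[:, None] * unit
    np.add.at(forces, i, f_pair)
    np.add.at(forces, j, -f_pair)
    return energy, forces


def langevin_step(coords: np.ndarray, forces: np.ndarray,
                  params: DynamicsParams,
                  rng: np.random.Generator | None = None,
                  step_index: int = 0) -> np.ndarray:
    """One overdamped Langevin (Brownian) update.

    With ``rng=None`` a fresh generator is seeded from ``params.seed``
    (single-step determinism); trajectory loops pass a persistent generator.
    """
    coords = np.asarray(coords, dtype=float)
    forces = np.asarray(forces, dtype=float)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    new = coords + params.mobility * forces
    if params.temperature > 0:
        new = new + params.noise_sigma * rng.standard_normal(coords.shape)
    if not np.all(np.isfinite(new)):
        raise DynamicsError(f"NaN/inf coordinates at step {step_index}")
    return new


def minimize(enm: ENM, coords: np.ndarray, max_steps: int = 500,
             gtol: float = 1e-6,
             restraint_centers: np.ndarray | None = None,
             restraint_k: float | np.ndarray = 0.0) -> np.ndarray:
    """Energy minimisation of the network (L-BFGS).

    Optional harmonic positional restraints of stiffness ``restraint_k``
    (scalar, or per-node array for e.g. quenching with part of the system
    held) toward ``restraint_centers`` regularise under-determined
    geometries.  Energy is non-increasing over accepted iterates; stops at
    the gradient tolerance or after ``max_steps`` iterations.
    """
    x0 = np.asarray(coords, dtype=float)
    shape = x0.shape
    k_r = np.asarray(restraint_k, dtype=float)
    if k_r.ndim == 1:
        k_r = k_r[:, None]

    def fun(flat: np.ndarray):
        xyz = flat.reshape(shape)
        energy, forces = enm_energy_forces(enm, xyz)
        grad = -forces
        if restraint_centers is not None and np.any(k_r > 0):
            dev = xyz - restraint_centers
            energy += 0.5 * float(np.sum(k_r * dev ** 2))
            grad = grad + k_r * dev
        return energy, grad.ravel()

    res = _scipy_minimize(fun, x0.ravel(), jac=True, method="L-BFGS-B",
                          options={"maxiter": max_steps, "gtol": gtol})
    return res.x.reshape(shape)
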