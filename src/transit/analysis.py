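"""Trajectory and structure metrics for transporter transitions.

Implements the analysis suite used to characterise an outward-facing to
inward-facing transition: residue contact maps and their differences,
Shrake–Rupley solvent-accessible surface area, HOLE-style pore-radius
profiles along the membrane normal, half-lumen water counts, salt-bridge
distance series, and per-selection best-fit RMSD series.

Definitions:

* two residues are in contact when any pair of their heavy atoms is within
  3.5 Å (inclusive), excluding pairs closer than 4 apart in sequence within
  one chain; inter-chain pairs are always eligible;
* a contact is *broken* when present in the "before" structure and absent in
  the "after" one, *formed* in the opposite case;
* the pore radius at height z is the largest clearance sphere centred in the
  plane at z: max over (x, y) of [min over atoms of (distance - vdW)],
  clamped at zero;
* the EC and IC lumen halves default to 2 ≤ z ≤ 15 and −15 ≤ z ≤ −2, and a
  water is counted when its oxygen lies in the half's window and within the
  proximity cutoff (default 10 Å) of the half's anchor atoms;
* a salt-bridge distance is the minimum distance between the acidic
  partner's side-chain oxygens and the basic partner's side-chain nitrogens.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize
from scipy.spatial import cKDTree

from .constants import ACIDIC_SIDECHAIN_O, BASIC_SIDECHAIN_N
from .errors import AnalysisError
from .geometry import best_fit_rmsd
from .structio import Selection, Structure, Trajectory

__all__ = [
    "ContactMap", "DifferentialContactMap", "RadiusProfile", "LumenSpec",
    "SaltBridgeSpec", "contact_set", "differential_contacts", "sasa",
    "pore_profile", "count_lumen_waters", "salt_bridge_distances",
    "rmsd_series",
]

ResidueKey = tuple[str, int]
Pair = tuple[ResidueKey, ResidueKey]


@dataclass(frozen=True)
class ContactMap:
    """Set of residue pairs in contact; each pair ordered (i before j)."""

    pairs: frozenset

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class DifferentialContactMap:
    broken: frozenset
    formed: frozenset

    def __post_init__(self) -> None:
        if self.broken & self.formed:
            raise ValueError("a pair cannot be both broken and formed")


@dataclass
class RadiusProfile:
    """Pore radius vs height; NaN marks slices where no bounded pore exists."""

    z: np.ndarray
    radius: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        if self.z.shape != self.radius.shape:
            raise ValueError("z and radius must have the same length")
        if np.any(np.diff(self.z) <= 0):
            raise ValueError("z must be strictly increasing")

    def mean_radius(self, z_lo: float, z_hi: float) -> float:
        mask = (self.z >= z_lo) & (self.z <= z_hi) & np.isfinite(self.radius)
        if not np.any(mask):
            return float("nan")
        return float(np.mean(self.radius[mask]))


@dataclass
class LumenSpec:
    """Geometric definition of the EC and IC lumen halves.

    z-windows are relative to the structure's frame origin; anchors are the
    lumen-lining atoms a counted water must be near.
    """

    ec_z: tuple[float, float] = (2.0, 15.0)
    ic_z: tuple[float, float] = (-15.0, -2.0)
    ec_anchors: Selection | None = None
    ic_anchors: Selection | None = None
    proximity_cutoff: float = 10.0

    def __post_init__(self) -> None:
        if self.proximity_cutoff <= 0:
            raise ValueError("proximity_cutoff must be positive")
        if self.ec_z[0] > self.ec_z[1] or self.ic_z[0] > self.ic_z[1]:
            raise ValueError("z windows must be (low, high)")
        if self.ic_z[1] > self.ec_z[0]:
            raise ValueError("EC window must lie above the IC window")


@dataclass
class SaltBridgeSpec:
    """An acidic/basic residue pair tracked by minimum side-chain N–O distance."""

    acidic: ResidueKey
    basic: ResidueKey
    distance_definition: str = "min-NO"


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------

def contact_set(structure: Structure, cutoff: float = 3.5,
                min_separation: int = 3) -> ContactMap:
    """Residue contact map over heavy protein atoms.

    A pair (i, j) is a contact when the minimum heavy-atom distance is at
    most ``cutoff`` (inclusive) and, within one chain, |i − j| exceeds
    ``min_separation``.  Waters are excluded.
    """
    idx = [k for k, a in enumerate(structure.atoms)
           if a.is_heavy and not a.is_water]
    if not idx:
        return ContactMap(frozenset())
    coords = structure.coords[idx]
    keys = [(structure.atoms[k].chain, structure.atoms[k].resid) for k in idx]
    tree = cKDTree(coords)
    pairs = set()
    for a, b in tree.query_pairs(cutoff):
        ka, kb = keys[a], keys[b]
        if ka == kb:
            continue
        if ka[0] == kb[0] and abs(ka[1] - kb[1]) <= min_separation:
            continue
        pairs.add((min(ka, kb), max(ka, kb)))
    return ContactMap(frozenset(pairs))


def differential_contacts(before: Structure, after: Structure,
                          cutoff: float = 3.5,
                          min_separation: int = 3) -> DifferentialContactMap:
    """Contacts broken and formed in ``after`` relative to ``before``."""
    if before.residue_keys() != after.residue_keys():
        raise AnalysisError("structures have different residue rosters")
    c_before = contact_set(before, cutoff, min_separation).pairs
    c_after = contact_set(after, cutoff, min_separation).pairs
    return DifferentialContactMap(broken=frozenset(c_before - c_after),
                                  formed=frozenset(c_after - c_before))


# ---------------------------------------------------------------------------
# SASA (Shrake-Rupley)
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points (Fibonacci lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def sasa(structure: Structure, selection: Selection, probe: float = 1.4,
         n_points: int = 960) -> float:
    """Solvent-accessible surface area (Å²) of a selection.

    Shrake–Rupley: each selected atom's sphere of radius (vdW + probe) is
    sampled at ``n_points`` quasi-uniform points; the accessible fraction
    times the sphere area is summed.  All atoms of the structure occlude.
    """
    if len(selection) == 0:
        warnings.warn("SASA of an empty selection is 0")
        return 0.0
    coords = structure.coords
    radii = np.array([a.vdw_radius for a in structure.atoms]) + probe
    tree = cKDTree(coords)
    unit = _sphere_points(n_points)
    max_r = radii.max()
    total = 0.0
    for i in selection.indices:
        r_i = radii[i]
        pts = coords[i] + r_i * unit
        neighbours = [j for j in tree.query_ball_point(coords[i], r_i + max_r)
                      if j != i]
        if neighbours:
            d2 = np.sum((pts[:, None, :] - coords[neighbours][None, :, :]) ** 2,
                        axis=2)
            # Exact surface ties (degenerate coincident atoms) are assigned
            # to the lower-indexed atom so shared surface is counted once.
            thr = (radii[neighbours] ** 2)[None, :] \
                + np.where(np.asarray(neighbours)[None, :] < i, 1e-9, -1e-9)
            buried = np.any(d2 < thr, axis=1)
            accessible = np.count_nonzero(~buried)
        else:
            accessible = n_points
        total += 4.0 * np.pi * r_i ** 2 * accessible / n_points
    return float(total)


# ---------------------------------------------------------------------------
# Pore radius profile (HOLE-style)
# ---------------------------------------------------------------------------

def pore_profile(structure: Structure, z_range: tuple[float, float] = (-15.0, 15.0),
                 dz: float = 0.5, optimizer_seed: int = 0,
                 n_restarts: int = 10, search_extent: float = 30.0,
                 heavy_only: bool = True) -> RadiusProfile:
    """Largest-clearance-sphere radius at each height along z.

    For each slice the clearance ``min_i(|p - c_i| - r_i)`` of a sphere
    centred at ``p = (x, y, z)`` is maximised over (x, y) by Nelder–Mead
    local searches seeded from the previous slice's centre plus random
    restarts.  Searches are confined to ``search_extent`` of the previous
    centre; a slice whose optimum escapes is reported as NaN (unbounded).
    Radii are clamped at 0.  Waters are never part of the wall.
    """
    z0 = structure.frame_axis_origin
    keep = [k for k, a in enumerate(structure.atoms)
            if not a.is_water and (a.is_heavy or not heavy_only)]
    if not keep:
        raise AnalysisError("no wall atoms for pore profile")
    coords = structure.coords[keep] - z0
    radii = np.array([structure.atoms[k].vdw_radius for k in keep])
    z_lo, z_hi = z_range
    zs = np.arange(z_lo, z_hi + 0.5 * dz, dz)
    slab = coords[(coords[:, 2] >= z_lo - 15.0) & (coords[:, 2] <= z_hi + 15.0)]
    if slab.shape[0] == 0:
        raise AnalysisError("structure is empty within the requested z range")
    rng = np.random.default_rng(optimizer_seed)
    centre = np.zeros(2)
    out = np.empty(len(zs))
    for k, z in enumerate(zs):
        def clearance(xy, _z=z):
            p = np.array([xy[0], xy[1], _z])
            return np.min(np.linalg.norm(coords - p, axis=1) - radii)

        starts = [centre]
        starts.extend(centre + rng.normal(scale=3.0, size=(n_restarts - 1, 2)))
        best_val = -np.inf
        best_xy = None
        for s in starts:
            res = _scipy_minimize(lambda xy: -clearance(xy), s,
                                  method="Nelder-Mead",
                                  options={"xatol": 1e-3, "fatol": 1e-4,
                                           "maxiter": 400})
            # A search that ran off into open space found no bounded pore:
            # discard the candidate rather than the slice.
            if np.any(np.abs(res.x - centre) > search_extent):
                continue
            if -res.fun > best_val:
                best_val = -res.fun
                best_xy = res.x
        if best_xy is None:
            out[k] = np.nan
        else:
            out[k] = max(best_val, 0.0)
            centre = best_xy
    return RadiusProfile(z=zs, radius=out)


# ---------------------------------------------------------------------------
# Lumen waters
# ---------------------------------------------------------------------------

def count_lumen_waters(structure: Structure, waters: Selection,
                       lumen: LumenSpec, half: str) -> int:
    """Number of water oxygens inside one lumen half.

    A water counts when its oxygen's z (relative to the frame origin) lies
    inside the half's window and the oxygen is within the proximity cutoff
    of at least one anchor atom.
    """
    half = half.upper()
    if half == "EC":
        window, anchors = lumen.ec_z, lumen.ec_anchors
    elif half == "IC":
        window, anchors = lumen.ic_z, lumen.ic_anchors
    else:
        raise ValueError("half must be 'EC' or 'IC'")
    if anchors is None or len(anchors) == 0:
        raise AnalysisError(f"{half} half has no anchors; criterion undefined")
    coords = structure.coords
    oxy = [i for i in waters.indices
           if structure.atoms[i].is_water
           and structure.atoms[i].element.upper() == "O"]
    if not oxy:
        return 0
    pts = coords[oxy]
    z = pts[:, 2] - structure.frame_axis_origin[2]
    in_window = (z >= window[0]) & (z <= window[1])
    anchor_xyz = coords[anchors.indices]
    tree = cKDTree(anchor_xyz)
    near = np.array([
        bool(tree.query_ball_point(p, lumen.proximity_cutoff)) for p in pts])
    return int(np.count_nonzero(in_window & near))


# ---------------------------------------------------------------------------
# Salt bridges
# ---------------------------------------------------------------------------

def _sidechain_atoms(structure: Structure, key: ResidueKey,
                     table: dict) -> list[int]:
    chain, resid = key
    resname = None
    hits = []
    for i, a in enumerate(structure.atoms):
        if a.chain == chain and a.resid == resid:
            resname = a.resname.upper()
            if resname in table and a.name in table[resname]:
                hits.append(i)
    if resname is None:
        raise AnalysisError(f"residue {chain}:{resid} not found")
    if resname not in table:
        raise AnalysisError(
            f"residue {chain}:{resid} ({resname}) is not of the expected "
            f"type ({'/'.join(table)})")
    if not hits:
        raise AnalysisError(
            f"residue {chain}:{resid} ({resname}) lacks side-chain atoms "
            f"{table[resname]}")
    return hits


def salt_bridge_distances(trajectory: Trajectory,
                          spec: SaltBridgeSpec) -> np.ndarray:
    """Per-frame minimum acidic-O ... basic-N side-chain distance (Å)."""
    if trajectory.template is None:
        raise AnalysisError("trajectory has no template structure")
    template = trajectory.template
    o_idx = _sidechain_atoms(template, spec.acidic, ACIDIC_SIDECHAIN_O)
    n_idx = _sidechain_atoms(template, spec.basic, BASIC_SIDECHAIN_N)
    o = trajectory.frames[:, o_idx, :]
    n = trajectory.frames[:, n_idx, :]
    d = np.linalg.norm(o[:, :, None, :] - n[:, None, :, :], axis=3)
    return d.reshape(trajectory.n_frames, -1).min(axis=1)


# ---------------------------------------------------------------------------
# RMSD series
# ---------------------------------------------------------------------------

def rmsd_series(trajectory: Trajectory, reference: Structure,
                selection: Selection) -> np.ndarray:
    """Best-fit RMSD of each frame to a reference over a selection (Å)."""
    idx = selection.indices
    if np.any(idx >= trajectory.n_atoms) or np.any(idx >= reference.n_atoms):
        raise AnalysisError("selection exceeds atom count")
    ref = reference.coords[idx]
    return np.array([best_fit_rmsd(frame[idx], ref)
                     for frame in trajectory.frames])
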