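"""Deterministic generators for all test inputs.

The generators emulate the structural situations a LeuT-fold transporter
presents to the analysis suite: a bundle of transmembrane helices around a
z-axial lumen, an outward-facing/inward-facing (OF/IF) state pair related by
a hinge bend of the intracellular halves of selected helices, pseudo-water
particles in the lumen halves, and analytic cylindrical cages for pore-radius
oracles.

Resolution: each residue carries a Cα and one pseudo-Cβ heavy atom placed
1.5 Å from the Cα along the outward normal of its helix, so contact and SASA
analyses see heavy-atom structure without full side chains.

Default geometry (chosen once as the package's standard study conditions):
10 helices of 24 residues (a realistic TM helix length) with ideal-helix
parameters (rise 1.5 Å/residue, twist 100°/residue, helix radius 2.3 Å) on a
ring tight enough that neighbouring helices form 3 Å-scale heavy-atom
contacts; the IF state bends helices TM2, TM5 and TM8 outward by 25° below
the membrane mid-plane, echoing the intracellular-opening motif of the
alternating-access transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .analysis import LumenSpec
from .errors import TransitError
from .structio import Atom, SegmentAnnotation, Selection, Structure

__all__ = ["BundleSpec", "HingeSpec", "make_bundle", "make_state_pair",
           "place_waters", "make_cylinder_fixture"]

HELIX_RADIUS = 2.3  # Å, Cα distance from the helix axis of an ideal α-helix
CB_OFFSET = 1.5     # Å, pseudo-Cβ distance from its Cα along the outward normal


@dataclass
class BundleSpec:
    """Geometry of an ideal α-helical bundle arranged on a ring about z."""

    n_helices: int = 10
    residues_per_helix: int = 24
    ring_radius: float = 12.5
    rise_per_residue: float = 1.5
    twist_per_residue: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_helices < 2:
            raise ValueError("need at least 2 helices")
        if self.residues_per_helix < 8:
            raise ValueError("need at least 8 residues per helix")


@dataclass
class HingeSpec:
    """Hinge bend turning an OF bundle into its IF counterpart.

    Atoms of the bent helices below ``hinge_z`` are rotated outward (away
    from the bundle axis) by ``bend_angle`` about a horizontal hinge axis at
    ``hinge_z``.  Two modes are supported:

    * ``"per-helix"`` (default): each helix rotates independently about the
      tangential axis through its own helix axis — individual helices
      splaying outward to open the intracellular lumen.
    * ``"block"``: the bent helices move as one rigid body about a common
      tangential axis through the group's centroid, emulating the
      rigid-body tilt of a helix bundle.
    """

    bent_helices: tuple[str, ...] = ("TM2", "TM5")
    hinge_z: float = 0.0
    bend_angle: float = 25.0
    mode: str = "per-helix"

    def __post_init__(self) -> None:
        if not 0.0 <= self.bend_angle <= 60.0:
            raise ValueError("bend_angle must be within [0, 60] degrees")
        if self.mode not in ("block", "per-helix"):
            raise ValueError("mode must be 'block' or 'per-helix'")
        self.bent_helices = tuple(self.bent_helices)


def _helix_axis_xy(spec: BundleSpec, h: int) -> np.ndarray:
    phi = 2.0 * np.pi * h / spec.n_helices
    return spec.ring_radius * np.array([np.cos(phi), np.sin(phi)])


def make_bundle(spec: BundleSpec) -> Structure:
    """Build an ideal helical bundle labelled TM1..TMn.

    Helices run parallel to z, centred on the membrane mid-plane (z = 0),
    with alternating N-to-C direction as in an antiparallel TM bundle.
    Deterministic for a given spec (the seed is carried for provenance and
    consumed only by generators that draw random numbers).
    """
    atoms: list[Atom] = []
    segments: dict[str, tuple[str, int, int]] = {}
    halves: dict[str, str] = {}
    m = spec.residues_per_helix
    serial = 0
    resid = 0
    for h in range(spec.n_helices):
        axis = _helix_axis_xy(spec, h)
        phi = 2.0 * np.pi * h / spec.n_helices
        start_resid = resid + 1
        direction = 1 if h % 2 == 0 else -1
        for i in range(m):
            resid += 1
            theta = np.deg2rad(spec.twist_per_residue) * i + phi
            z = direction * (i - (m - 1) / 2.0) * spec.rise_per_residue
            radial = np.array([np.cos(theta), np.sin(theta)])
            ca_xy = axis + HELIX_RADIUS * radial
            ca = np.array([ca_xy[0], ca_xy[1], z])
            cb = np.array([*(axis + (HELIX_RADIUS + CB_OFFSET) * radial), z])
            serial += 1
            atoms.append(Atom(serial, "CA", "C", resid, "ALA", "A", ca))
            serial += 1
            atoms.append(Atom(serial, "CB", "C", resid, "ALA", "A", cb))
        label = f"TM{h + 1}"
        segments[label] = ("A", start_resid, resid)
        halves[label] = "both"
    annotation = SegmentAnnotation(segments=segments, half_assignment=halves)
    return Structure(atoms, annotation, frame_axis_origin=np.zeros(3))


def make_state_pair(bundle: Structure,
                    hinge: HingeSpec) -> tuple[Structure, Structure]:
    """Return (OF state, IF state) related by the hinge bend.

    The OF state is the bundle itself.  In the IF state every atom of a bent
    helix lying below ``hinge_z`` is rotated outward by ``bend_angle`` about
    a tangential axis through the helix axis at the hinge height; atoms at or
    above ``hinge_z`` are bitwise identical between the two states.  The
    residue roster and annotation are preserved exactly.
    """
    ann = bundle.annotation
    for label in hinge.bent_helices:
        if label not in ann.segments:
            raise TransitError(
                f"unknown helix label {label!r}; known: {', '.join(ann.labels)}")
    of_state = bundle.copy()
    if_state = bundle.copy()
    angle = np.deg2rad(hinge.bend_angle)
    origin_xy = bundle.frame_axis_origin[:2]

    def helix_atoms_of(label: str) -> list[Atom]:
        chain, resids = ann.residues_of(label)
        resid_set = set(resids)
        return [a for a in if_state.atoms
                if a.chain == chain and a.resid in resid_set]

    def outward_rotation(axis_xy: np.ndarray) -> tuple[Rotation, np.ndarray]:
        radial = axis_xy - origin_xy
        nrm = np.linalg.norm(radial)
        if nrm < 1e-9:
            raise TransitError("hinge pivot sits on the bundle axis; "
                               "outward direction undefined")
        radial = radial / nrm
        # Tangential axis; rotation by -angle about (z x r) tilts the lower
        # half outward along +r.
        tangent = np.array([-radial[1], radial[0], 0.0])
        rot = Rotation.from_rotvec(-angle * tangent)
        pivot = np.array([axis_xy[0], axis_xy[1], hinge.hinge_z])
        return rot, pivot

    if hinge.mode == "block":
        groups = [[a for label in hinge.bent_helices
                   for a in helix_atoms_of(label)]]
    else:
        groups = [helix_atoms_of(label) for label in hinge.bent_helices]
    for group in groups:
        axis_xy = np.mean([a.coords[:2] for a in group if a.name == "CA"],
                          axis=0)
        rot, pivot = outward_rotation(axis_xy)
        for atom in group:
            if atom.coords[2] < hinge.hinge_z:
                atom.coords = rot.apply(atom.coords - pivot) + pivot
    return of_state, if_state


def place_waters(structure: Structure, lumen: LumenSpec, half: str, n: int,
                 seed: int = 0, anchor_cutoff: float = 8.0,
                 min_clearance: float = 2.4, max_tries: int = 20000) -> Structure:
    """Add ``n`` water oxygens inside one lumen half.

    Waters are rejection-sampled uniformly within ``anchor_cutoff`` of the
    half's anchor atoms, constrained to the half's z-window and to a minimum
    clearance from every existing atom (and from each other).  Raises with
    the achieved count if the region is too crowded.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    out = structure.copy()
    if n == 0:
        return out
    half = half.upper()
    if half == "EC":
        z_lo, z_hi = lumen.ec_z
        anchors = lumen.ec_anchors
    elif half == "IC":
        z_lo, z_hi = lumen.ic_z
        anchors = lumen.ic_anchors
    else:
        raise ValueError("half must be 'EC' or 'IC'")
    if anchors is None or len(anchors) == 0:
        raise TransitError("lumen half has no anchor atoms")
    rng = np.random.default_rng(seed)
    coords = structure.coords
    anchor_xyz = coords[anchors.indices]
    z0 = structure.frame_axis_origin[2]
    placed: list[np.ndarray] = []
    occupied = coords
    next_serial = max((a.serial for a in out.atoms), default=0)
    next_resid = 0
    tries = 0
    while len(placed) < n:
        if tries >= max_tries:
            raise TransitError(
                f"could only place {len(placed)} of {n} waters in the {half} "
                f"half after {max_tries} attempts")
        tries += 1
        anchor = anchor_xyz[rng.integers(len(anchor_xyz))]
        offset = rng.uniform(-anchor_cutoff, anchor_cutoff, size=3)
        if np.linalg.norm(offset) > anchor_cutoff:
            continue
        point = anchor + offset
        z_rel = point[2] - z0
        if not (z_lo <= z_rel <= z_hi):
            continue
        if np.min(np.linalg.norm(anchor_xyz - point, axis=1)) > anchor_cutoff:
            continue
        if np.min(np.linalg.norm(occupied - point, axis=1)) < min_clearance:
            continue
        if placed and np.min(np.linalg.norm(np.array(placed) - point,
                                            axis=1)) < min_clearance:
            continue
        placed.append(point)
        next_serial += 1
        next_resid += 1
        out.atoms.append(Atom(next_serial, "O", "O", next_resid, "HOH", "W",
                              point, is_water=True))
    return out


def make_cylinder_fixture(ring_radius: float | list[float], n_rings: int = 20,
                          atoms_per_ring: int = 36, vdw: float = 1.7,
                          ring_spacing: float = 1.0) -> Structure:
    """Stacked rings of atoms about z: an analytic pore-radius oracle.

    With a constant ring radius R the pore radius is exactly ``R - vdw`` on
    the axis at every height.  ``ring_radius`` may be a sequence of per-ring
    radii to build constrictions.  Rings are centred on z = 0.
    """
    if np.isscalar(ring_radius):
        radii = [float(ring_radius)] * n_rings
    else:
        radii = [float(r) for r in ring_radius]
        n_rings = len(radii)
    if min(radii) <= vdw:
        raise ValueError("ring radius must exceed the vdW radius")
    atoms: list[Atom] = []
    serial = 0
    for j, r in enumerate(radii):
        z = (j - (n_rings - 1) / 2.0) * ring_spacing
        for i in range(atoms_per_ring):
            theta = 2.0 * np.pi * i / atoms_per_ring \
                + (np.pi / atoms_per_ring) * (j % 2)
            serial += 1
            atoms.append(Atom(serial, "C", "C", j + 1, "CYL", "A",
                              np.array([r * np.cos(theta), r * np.sin(theta), z]),
                              vdw_radius=vdw))
    return Structure(atoms, frame_axis_origin=np.zeros(3))


def default_lumen_spec(structure: Structure) -> LumenSpec:
    """Lumen specification for generated bundles.

    Anchors are the Cα atoms of all helices within each half's z-window —
    the generated analogue of anchoring water counts to the lumen-lining
    helices.
    """
    coords = structure.coords
    z = coords[:, 2] - structure.frame_axis_origin[2]
    names = np.array([a.name for a in structure.atoms])
    ec = np.flatnonzero((names == "CA") & (z >= 2) & (z <= 15))
    ic = np.flatnonzero((names == "CA") & (z >= -15) & (z <= -2))
    return LumenSpec(ec_anchors=Selection(ec), ic_anchors=Selection(ic))
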