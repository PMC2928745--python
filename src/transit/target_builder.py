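"""Threading of a hybrid conformational target ("pre-target").

A subject structure (e.g. the outward-facing crystal state) is threaded onto
a template in another conformational state via a residue-correspondence map
derived from a gapped two-sequence alignment.  Paired residues adopt the
template's Cα positions (after a global best-fit of the template onto the
subject, so the product lives in the subject's membrane frame); segments
listed as retain-subject keep the subject's own geometry and are stitched in
by superposing them on flanking paired anchor residues.  The result is a
Cα-resolution target for the biased dynamics stage, optionally regularised
by a short restrained minimisation under the subject-topology network.

Alignment computation itself (structure-based alignment) is an input, not a
product: this module parses and edits its result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .cg_model import ENM, minimize as enm_minimize
from .errors import AlignmentError, TransitError
from .geometry import kabsch_superpose
from .structio import Structure

__all__ = ["AlignmentMap", "Edit", "RemoveGaps", "ShiftSegmentStart",
           "AddRetainSubject", "parse_alignment", "adjust_alignment",
           "thread_target", "regularize_target"]


@dataclass(frozen=True)
class AlignmentMap:
    """One-to-one residue correspondence subject ↔ template.

    ``pairs`` is strictly increasing in both columns (collinear alignment);
    ``retain_subject`` ranges (inclusive) are modelled from the subject and
    must not overlap paired subject residues.
    """

    pairs: tuple
    retain_subject: tuple = ()

    def __post_init__(self) -> None:
        pairs = tuple((int(s), int(t)) for s, t in self.pairs)
        retain = tuple((int(a), int(b)) for a, b in self.retain_subject)
        object.__setattr__(self, "pairs", pairs)
        object.__setattr__(self, "retain_subject", retain)
        for (s1, t1), (s2, t2) in zip(pairs, pairs[1:]):
            if s2 <= s1 or t2 <= t1:
                raise AlignmentError(
                    f"pairs must be strictly increasing in both columns; "
                    f"({s1},{t1}) then ({s2},{t2})")
        paired = {s for s, _ in pairs}
        seen: set[int] = set()
        for a, b in retain:
            if a > b:
                raise AlignmentError(f"retain range {a}-{b} reversed")
            r = set(range(a, b + 1))
            if r & paired:
                raise AlignmentError(
                    f"retain range {a}-{b} overlaps paired subject residues")
            if r & seen:
                raise AlignmentError(f"retain range {a}-{b} overlaps another")
            seen |= r

    @property
    def subject_of_template(self) -> dict[int, int]:
        return {t: s for s, t in self.pairs}

    @property
    def template_of_subject(self) -> dict[int, int]:
        return dict(self.pairs)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def parse_alignment(fasta_path, overrides_path=None,
                    subject_start: int = 1,
                    template_start: int = 1) -> AlignmentMap:
    """Build an :class:`AlignmentMap` from a gapped two-record FASTA.

    The first record is the subject, the second the template.  Non-gap
    columns shared by both sequences become pairs; residue numbering starts
    at ``subject_start`` / ``template_start``.  The optional overrides file
    is a TSV of ``range<TAB>action`` rows; action ``retain`` adds the
    subject range to ``retain_subject``.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 2:
        raise AlignmentError(
            f"{fasta_path}: expected exactly 2 records, found {len(records)}")
    subj, tmpl = str(records[0].seq), str(records[1].seq)
    if len(subj) != len(tmpl):
        raise AlignmentError(
            f"{fasta_path}: aligned lengths differ ({len(subj)} vs {len(tmpl)})")
    pairs = []
    s = subject_start - 1
    t = template_start - 1
    for cs, ct in zip(subj, tmpl):
        s_res = cs not in "-."
        t_res = ct not in "-."
        if s_res:
            s += 1
        if t_res:
            t += 1
        if s_res and t_res:
            pairs.append((s, t))
    retain = []
    if overrides_path is not None:
        with open(overrides_path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                try:
                    rng, action = line.split("\t")
                    lo, hi = (int(x) for x in rng.split("-"))
                except ValueError as exc:
                    raise AlignmentError(
                        f"{overrides_path}: bad override at line {lineno}: "
                        f"{line!r}") from exc
                if action.strip().lower() != "retain":
                    raise AlignmentError(
                        f"{overrides_path}: unknown action {action!r} at "
                        f"line {lineno}")
                retain.append((lo, hi))
    return AlignmentMap(pairs=tuple(pairs), retain_subject=tuple(retain))


# ---------------------------------------------------------------------------
# Edits
# ---------------------------------------------------------------------------

class Edit:
    """Base class of alignment edits; subclasses implement ``apply``."""

    def apply(self, amap: AlignmentMap) -> tuple[AlignmentMap, str]:
        raise NotImplementedError


@dataclass(frozen=True)
class RemoveGaps(Edit):
    """Re-pair a subject range contiguously, closing internal gaps.

    Used where a continuous helix in the subject must not be interrupted by
    alignment gaps: every subject residue between the range's first and last
    paired residue is paired consecutively against the template run starting
    at the first paired template residue.
    """

    subject_start: int
    subject_end: int

    def apply(self, amap: AlignmentMap) -> tuple[AlignmentMap, str]:
        inside = [(s, t) for s, t in amap.pairs
                  if self.subject_start <= s <= self.subject_end]
        if not inside:
            return amap, (f"remove-gaps {self.subject_start}-{self.subject_end}: "
                          f"no pairs in range, no-op")
        s_lo, t0 = inside[0]
        s_hi = inside[-1][0]
        new_inside = [(s, t0 + (s - s_lo)) for s in range(s_lo, s_hi + 1)]
        outside = [(s, t) for s, t in amap.pairs
                   if not (self.subject_start <= s <= self.subject_end)]
        merged = sorted(outside + new_inside)
        try:
            out = AlignmentMap(tuple(merged), amap.retain_subject)
        except AlignmentError as exc:
            raise AlignmentError(
                f"remove-gaps {self.subject_start}-{self.subject_end} breaks "
                f"alignment monotonicity: {exc}") from exc
        return out, (f"remove-gaps {self.subject_start}-{self.subject_end}: "
                     f"re-paired {len(new_inside)} residues contiguously")


@dataclass(frozen=True)
class ShiftSegmentStart(Edit):
    """Slide the template partners of a subject segment by ``offset``.

    Used to move the starting position of a helix alignment; the inverse
    shift restores the original map.
    """

    subject_start: int
    subject_end: int
    offset: int

    def apply(self, amap: AlignmentMap) -> tuple[AlignmentMap, str]:
        shifted = []
        n_shifted = 0
        for s, t in amap.pairs:
            if self.subject_start <= s <= self.subject_end:
                shifted.append((s, t + self.offset))
                n_shifted += 1
            else:
                shifted.append((s, t))
        try:
            out = AlignmentMap(tuple(shifted), amap.retain_subject)
        except AlignmentError as exc:
            raise AlignmentError(
                f"shift-segment-start {self.subject_start}-{self.subject_end} "
                f"by {self.offset:+d} breaks monotonicity: {exc}") from exc
        return out, (f"shift-segment-start {self.subject_start}-"
                     f"{self.subject_end} by {self.offset:+d} "
                     f"({n_shifted} pairs)")


@dataclass(frozen=True)
class AddRetainSubject(Edit):
    """Model a subject range from the subject itself (e.g. an unmatched loop)."""

    subject_start: int
    subject_end: int

    def apply(self, amap: AlignmentMap) -> tuple[AlignmentMap, str]:
        retain = amap.retain_subject + ((self.subject_start, self.subject_end),)
        out = AlignmentMap(amap.pairs, retain)  # invariants re-checked
        return out, (f"add-retain-subject {self.subject_start}-"
                     f"{self.subject_end}")


def adjust_alignment(amap: AlignmentMap,
                     edits: list[Edit]) -> tuple[AlignmentMap, list[str]]:
    """Apply edits in order; returns the edited map and an edit log."""
    log: list[str] = []
    for edit in edits:
        amap, entry = edit.apply(amap)
        log.append(entry)
    return amap, log


# ---------------------------------------------------------------------------
# Threading
# ---------------------------------------------------------------------------

def _ca_index(structure: Structure) -> dict[tuple[str, int], int]:
    out = {}
    for i, a in enumerate(structure.atoms):
        if a.name == "CA":
            out[(a.chain, a.resid)] = i
    return out


def _residue_atoms(structure: Structure) -> dict[tuple[str, int], list[int]]:
    out: dict[tuple[str, int], list[int]] = {}
    for i, a in enumerate(structure.atoms):
        out.setdefault((a.chain, a.resid), []).append(i)
    return out


def thread_target(subject: Structure, template: Structure,
                  amap: AlignmentMap, subject_chain: str = "A",
                  template_chain: str = "A",
                  n_anchors: int = 3) -> Structure:
    """Thread subject coordinates onto the template conformation.

    Paired residues take the template residue's Cα position after a global
    best-fit pre-alignment of the template onto the subject over all paired
    residues (each residue's remaining atoms are convected with its Cα);
    retain-subject segments keep the subject's internal geometry and are
    stitched in by superposing segment-plus-anchors on the flanking paired
    residues (up to ``n_anchors`` per side; fewer at termini with a warning,
    none at all is an error).  The product carries the subject's annotation.
    """
    if len(amap.pairs) < 3:
        raise TransitError(
            "threading requires at least 3 paired residues (and retained "
            "segments need paired anchors)")
    subj_ca = _ca_index(subject)
    tmpl_ca = _ca_index(template)
    for s, t in amap.pairs:
        if (subject_chain, s) not in subj_ca:
            raise TransitError(f"subject residue {s} has no Cα")
        if (template_chain, t) not in tmpl_ca:
            raise TransitError(f"template residue {t} has no Cα")
    subj_coords = subject.coords
    tmpl_coords = template.coords
    s_idx = np.array([subj_ca[(subject_chain, s)] for s, _ in amap.pairs])
    t_idx = np.array([tmpl_ca[(template_chain, t)] for _, t in amap.pairs])
    sup = kabsch_superpose(tmpl_coords[t_idx], subj_coords[s_idx])
    tmpl_in_subj = sup.transform(tmpl_coords)

    out = subject.copy()
    res_atoms = _residue_atoms(subject)
    new_coords = subject.coords
    paired_subject = [s for s, _ in amap.pairs]
    for (s, t) in amap.pairs:
        ca_s = subj_ca[(subject_chain, s)]
        target_ca = tmpl_in_subj[tmpl_ca[(template_chain, t)]]
        shift = target_ca - subj_coords[ca_s]
        for ai in res_atoms[(subject_chain, s)]:
            new_coords[ai] = subj_coords[ai] + shift

    for lo, hi in amap.retain_subject:
        before = [s for s in paired_subject if s < lo][-n_anchors:]
        after = [s for s in paired_subject if s > hi][:n_anchors]
        anchors = before + after
        if not anchors:
            raise TransitError(
                f"retained segment {lo}-{hi} has no paired anchor residues")
        if len(before) < n_anchors or len(after) < n_anchors:
            warnings.warn(
                f"retained segment {lo}-{hi}: only {len(before)}+{len(after)} "
                f"anchor residues available")
        anchor_idx = [subj_ca[(subject_chain, s)] for s in anchors
                      if (subject_chain, s) in subj_ca]
        if not anchor_idx:
            raise TransitError(
                f"retained segment {lo}-{hi}: anchors lack Cα atoms")
        src = subj_coords[anchor_idx]
        dst = new_coords[anchor_idx]
        seg_atoms = [ai for s in range(lo, hi + 1)
                     for ai in res_atoms.get((subject_chain, s), [])]
        if not seg_atoms:
            raise TransitError(f"retained segment {lo}-{hi} has no atoms")
        if len(anchor_idx) >= 3:
            try:
                seg_sup = kabsch_superpose(src, dst)
                new_coords[seg_atoms] = seg_sup.transform(subj_coords[seg_atoms])
            except Exception:
                new_coords[seg_atoms] = subj_coords[seg_atoms] \
                    + (dst.mean(axis=0) - src.mean(axis=0))
        else:
            new_coords[seg_atoms] = subj_coords[seg_atoms] \
                + (dst.mean(axis=0) - src.mean(axis=0))
    out.set_coords(new_coords)
    return out


def regularize_target(threaded: Structure, enm_of_subject: ENM,
                      restraint_k: float = 0.1, max_steps: int = 500,
                      bond_range: tuple[float, float] = (3.4, 4.2)) -> Structure:
    """Relax a threaded target under the subject-topology network.

    A short minimisation of the subject-built ENM with harmonic restraints
    toward the threaded positions smooths stitching artefacts (e.g. stretched
    junctions) without abandoning the threaded conformation.  Warns when
    consecutive-Cα distances remain outside ``bond_range``.
    """
    node_idx = enm_of_subject.node_selection.indices
    coords = threaded.coords
    x0 = coords[node_idx]
    x = enm_minimize(enm_of_subject, x0, max_steps=max_steps,
                     restraint_centers=x0, restraint_k=restraint_k)
    out = threaded.copy()
    new_coords = coords.copy()
    disp = x - x0
    # Convect each residue's remaining atoms with its node.
    node_of_residue = {}
    for local, ai in enumerate(node_idx):
        a = threaded.atoms[ai]
        node_of_residue[(a.chain, a.resid)] = local
    for ai, a in enumerate(threaded.atoms):
        local = node_of_residue.get((a.chain, a.resid))
        if local is not None:
            new_coords[ai] = coords[ai] + disp[local]
    out.set_coords(new_coords)

    # Bonded-geometry check: consecutive residues within one annotated
    # segment (numbering may jump chains/segments without a physical bond).
    segments = threaded.annotation.segments

    def same_segment(chain, r1, r2):
        if not segments:
            return True
        return any(c == chain and s <= r1 <= e and s <= r2 <= e
                   for c, s, e in segments.values())

    ca = [(a.chain, a.resid, i) for i, a in enumerate(out.atoms)
          if a.name == "CA"]
    for (c1, r1, i1), (c2, r2, i2) in zip(ca, ca[1:]):
        if c1 == c2 and r2 == r1 + 1 and same_segment(c1, r1, r2):
            d = float(np.linalg.norm(new_coords[i2] - new_coords[i1]))
            if not bond_range[0] <= d <= bond_range[1]:
                warnings.warn(
                    f"consecutive Cα distance {d:.2f} Å between {c1}:{r1} and "
                    f"{c2}:{r2} outside {bond_range} after regularisation")
    return out
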