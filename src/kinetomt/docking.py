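"""Superposition-based docking of the Ndc80c rod onto the lattice.

Two operations reproduce the composite-model workflow:

``transplant_pose``
    Shared-template docking: a reference complex contains a receptor part
    (e.g. tubulin) bound to a ligand part (e.g. the Ndc80:Nuf2 head).  The
    receptor part is superposed onto an equivalent site in the target
    lattice, which carries the ligand pose along; a free-standing ligand
    model is then superposed onto that carried pose.  The same mechanism
    grafts the C-terminal Dam1 segment onto the docked head.

``set_hinge``
    The Ndc80c rod bends at a hinge (Ndc80 residue 412 / Nuf2 residue 245,
    ~160 A from the globular head).  Given a rod whose head-proximal
    segment is already placed, the distal segment is rotated about the
    hinge so its principal axis makes a requested angle with a reference
    axis — 0 deg to the tube axis for the "approximately parallel"
    arrangement of the shaft and the Spc24:Spc25 end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, InvalidArgumentError, MatchError, PlacementError
from .geometry import RigidTransform, angle_between, axis_rotation, superpose
from .structures import Selection, StructureModel, merge, select

__all__ = ["BindingTemplate", "HingedRod", "transplant_pose", "set_hinge"]


@dataclass
class BindingTemplate:
    """A bound reference complex split into receptor and ligand selections."""

    reference_complex: StructureModel
    receptor_selection: list[Selection]
    ligand_selection: list[Selection]

    def __post_init__(self):
        if isinstance(self.receptor_selection, Selection):
            self.receptor_selection = [self.receptor_selection]
        if isinstance(self.ligand_selection, Selection):
            self.ligand_selection = [self.ligand_selection]
        rec = {
            (s.chain_id, lo, hi) for s in self.receptor_selection for lo, hi in s.ranges
        }
        lig = {(s.chain_id, lo, hi) for s in self.ligand_selection for lo, hi in s.ranges}
        if not rec or not lig:
            raise InvalidArgumentError("receptor and ligand selections must be non-empty")
        for c, lo, hi in rec:
            for c2, lo2, hi2 in lig:
                if c == c2 and lo <= hi2 and lo2 <= hi:
                    raise InvalidArgumentError(
                        f"receptor and ligand selections overlap on chain {c} ({lo}-{hi})"
                    )


@dataclass
class HingedRod:
    """Two-segment rod with named junction selections at the hinge."""

    segment_a: StructureModel
    segment_b: StructureModel
    hinge_a: list[Selection]
    hinge_b: list[Selection]

    def __post_init__(self):
        if isinstance(self.hinge_a, Selection):
            self.hinge_a = [self.hinge_a]
        if isinstance(self.hinge_b, Selection):
            self.hinge_b = [self.hinge_b]


def _keyed_atoms(model: StructureModel, selections, atom_names=("CA",)):
    """Map (chain, resnum, atom name) -> position over the given selections."""
    out = {}
    for sel in selections:
        sub = select(model, sel)
        for ch, res, atom in sub.iter_atoms():
            if atom_names is not None and atom.name not in atom_names:
                continue
            out[(ch.chain_id, res.seqnum, atom.name)] = atom.position
    return out


def transplant_pose(
    template: BindingTemplate,
    target_receptor_site: StructureModel,
    ligand: StructureModel,
    atom_names: tuple[str, ...] = ("CA",),
) -> tuple[RigidTransform, float]:
    """Dock ``ligand`` onto ``target_receptor_site`` via the bound template.

    Returns ``(transform, receptor_rmsd)``: applying the transform to the
    ligand yields the docked pose; the RMSD is that of the template-receptor
    onto the target site.  Atom matching uses (chain, residue number, atom
    name) keys, CA-only by default.

    Raises
    ------
    MatchError
        If any template-receptor residue has no counterpart in the target
        site (the unmatched keys are listed), or the ligand cannot be
        matched to the template's ligand part.
    """
    tmpl_rec = _keyed_atoms(template.reference_complex, template.receptor_selection, atom_names)
    target_rec = _keyed_atoms(target_receptor_site, template.receptor_selection, atom_names)
    missing = sorted(k for k in tmpl_rec if k not in target_rec)
    if missing or not tmpl_rec:
        raise MatchError(
            f"target site is missing {len(missing)} receptor atoms, e.g. {missing[:5]}",
            unmatched=missing,
        )
    keys = sorted(tmpl_rec)
    t_rec, rec_rmsd = superpose(
        np.stack([tmpl_rec[k] for k in keys]), np.stack([target_rec[k] for k in keys])
    )

    tmpl_lig = _keyed_atoms(template.reference_complex, template.ligand_selection, atom_names)
    lig_atoms = _keyed_atoms(ligand, template.ligand_selection, atom_names)
    shared = sorted(k for k in tmpl_lig if k in lig_atoms)
    if len(shared) < 3:
        raise MatchError(
            f"ligand shares only {len(shared)} atoms with the template ligand selection",
            unmatched=sorted(set(tmpl_lig) - set(lig_atoms)),
        )
    placed_lig = t_rec.apply(np.stack([tmpl_lig[k] for k in shared]))
    t_lig, _ = superpose(np.stack([lig_atoms[k] for k in shared]), placed_lig)
    return t_lig, rec_rmsd


def _junction_centroid(model: StructureModel, selections) -> np.ndarray:
    pts = _keyed_atoms(model, selections, atom_names=None)
    if not pts:
        raise InvalidArgumentError("hinge junction selection resolves to no atoms")
    return np.stack(list(pts.values())).mean(axis=0)


def _principal_axis(model: StructureModel, away_from: np.ndarray) -> np.ndarray:
    coords = model.coords()
    centered = coords - coords.mean(axis=0)
    if coords.shape[0] < 2:
        raise DegenerateInputError("segment has too few atoms for a principal axis")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if np.dot(axis, coords.mean(axis=0) - away_from) < 0:
        axis = -axis
    return axis


def set_hinge(
    rod: HingedRod,
    hinge_angle: float,
    reference_axis,
    angle_tol: float = 0.1,
    max_junction_gap: float = 2.0,
) -> StructureModel:
    """Rotate the distal segment about the hinge to a requested axis angle.

    The pivot is the centroid of the ``hinge_a`` junction atoms; the distal
    segment is rotated in the plane spanned by its current principal axis
    and ``reference_axis`` until the angle between them equals
    ``hinge_angle`` (degrees).  Internal coordinates of both segments are
    untouched.  Returns the merged rod (same-id chains are concatenated).

    Raises
    ------
    PlacementError
        If the requested angle is outside [0, 180] or the junction gap
        after placement exceeds ``max_junction_gap`` (Angstrom).
    """
    if not 0.0 <= hinge_angle <= 180.0:
        raise PlacementError(f"hinge angle {hinge_angle} outside [0, 180]", hinge_angle)
    ref = np.asarray(reference_axis, dtype=float).reshape(3)
    if np.linalg.norm(ref) < 1e-12:
        raise InvalidArgumentError("reference axis must be non-zero")
    ref = ref / np.linalg.norm(ref)

    pivot = _junction_centroid(rod.segment_a, rod.hinge_a)
    axis_b = _principal_axis(rod.segment_b, away_from=pivot)
    current = angle_between(axis_b, ref)

    delta = current - hinge_angle
    if abs(delta) < 1e-12:
        placed_b = rod.segment_b.copy()
    else:
        n = np.cross(axis_b, ref)
        if np.linalg.norm(n) < 1e-9:  # parallel: any perpendicular axis works
            helper = np.array([1.0, 0.0, 0.0])
            if abs(np.dot(helper, ref)) > 0.9:
                helper = np.array([0.0, 1.0, 0.0])
            n = np.cross(ref, helper)
        n = n / np.linalg.norm(n)
        # rotating by +delta about n moves axis_b toward ref by delta degrees
        placed_b = rod.segment_b.transformed(axis_rotation(n, delta, pivot))
        achieved = angle_between(_principal_axis(placed_b, away_from=pivot), ref)
        if abs(achieved - hinge_angle) > angle_tol:
            # sign convention of the plane normal may oppose the turn direction
            placed_b = rod.segment_b.transformed(axis_rotation(n, -delta, pivot))
            achieved = angle_between(_principal_axis(placed_b, away_from=pivot), ref)
            if abs(achieved - hinge_angle) > angle_tol:
                raise PlacementError(
                    f"could not reach hinge angle {hinge_angle} deg "
                    f"(achieved {achieved:.3f} deg)",
                    achieved,
                )

    gap = float(
        np.linalg.norm(_junction_centroid(placed_b, rod.hinge_b) - pivot)
    )
    if gap > max_junction_gap:
        raise PlacementError(
            f"junction gap {gap:.2f} A exceeds {max_junction_gap} A after placement"
        )
    merged = merge([rod.segment_a, placed_b], chain_relabel_policy="merge")
    merged.metadata = dict(rod.segment_a.metadata)
    merged.metadata.update(
        {k: v for k, v in rod.segment_b.metadata.items() if k not in merged.metadata}
    )
    merged.metadata["hinge_angle"] = hinge_angle
    return merged
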