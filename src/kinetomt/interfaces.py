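"""Contact, salt-bridge and phosphorylation-conflict analysis of an interface.

Implements the geometric reading of the Dam1 C-terminus : Ndc80 head
contact: which residue pairs touch, which basic/acidic pairs form salt
bridges (the conserved Dam1 Arg299 - Ndc80 Asp295 anchor), and which
Ser/Thr sites would, upon phosphorylation by Ipl1/Aurora B, place a
phosphate against an acidic partner (Ser257 opposite Ndc80 Glu276) and so
weaken the interface.  Sites with no partner atoms nearby are reported as
"exposed" — sterically free to be phosphorylated without a predicted
structural conflict, like Dam1 Ser292.

All scans operate on residue-level minimum distances between heavy atoms;
coarse-grained chains (one CA pseudo-atom per residue) are handled by
falling back to CA as the charged-group or hydroxyl reference atom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import SelectionError, ValidationError
from .structures import Selection, StructureModel, select

__all__ = [
    "InterfaceReport",
    "find_contacts",
    "find_salt_bridges",
    "phospho_conflict_scan",
    "analyze_interface",
]

BASIC_RESIDUES = ("ARG", "LYS", "HIS")
ACIDIC_RESIDUES = ("ASP", "GLU")

DEFAULT_CONTACT_CUTOFF = 4.0
DEFAULT_SALT_BRIDGE_CUTOFF = 4.0
DEFAULT_PHOSPHO_CUTOFF = 6.0  # phosphate adds reach beyond the hydroxyl
DEFAULT_EXPOSURE_RADIUS = 8.0


@dataclass(frozen=True)
class ResidueRef:
    chain_id: str
    seqnum: int
    name: str

    def __str__(self):
        return f"{self.chain_id}/{self.name}{self.seqnum}"


@dataclass
class InterfaceReport:
    contacts: list[tuple[ResidueRef, ResidueRef, float]] = field(default_factory=list)
    salt_bridges: list[tuple[ResidueRef, ResidueRef, float]] = field(default_factory=list)
    phospho_conflicts: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "contacts": [
                {"residue_a": str(a), "residue_b": str(b), "distance": round(d, 3)}
                for a, b, d in self.contacts
            ],
            "salt_bridges": [
                {"basic": str(a), "acidic": str(b), "distance": round(d, 3)}
                for a, b, d in self.salt_bridges
            ],
            "phospho_conflicts": self.phospho_conflicts,
        }


def _group_residues(model: StructureModel, sel: Selection):
    """Residues of a selection as (ResidueRef, positions array, residue) triples."""
    sub = select(model, sel)
    out = []
    for ch in sub.chains:
        for res in ch.residues:
            ref = ResidueRef(ch.chain_id, res.seqnum, res.name)
            out.append((ref, np.stack([a.position for a in res.atoms]), res))
    if not out:
        raise SelectionError(
            f"selection {sel.chain_id}:{sel.ranges} resolves to no residues"
        )
    return out


def find_contacts(
    model: StructureModel,
    group_a: Selection,
    group_b: Selection,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> list[tuple[ResidueRef, ResidueRef, float]]:
    """Residue pairs whose minimum heavy-atom distance is <= ``cutoff``.

    Symmetric in the two groups; each pair is reported once, as
    (residue_of_a, residue_of_b, min distance).
    """
    res_a = _group_residues(model, group_a)
    res_b = _group_residues(model, group_b)
    coords_b = np.concatenate([pts for _, pts, _ in res_b])
    owner_b = np.concatenate(
        [np.full(len(pts), i) for i, (_, pts, _) in enumerate(res_b)]
    )
    tree = cKDTree(coords_b)
    found: dict[tuple[int, int], float] = {}
    for ia, (_, pts_a, _) in enumerate(res_a):
        for pt in pts_a:
            for ib_atom in tree.query_ball_point(pt, cutoff):
                d = float(np.linalg.norm(pt - coords_b[ib_atom]))
                if d <= cutoff:
                    key = (ia, int(owner_b[ib_atom]))
                    if d < found.get(key, np.inf):
                        found[key] = d
    return sorted(
        [(res_a[ia][0], res_b[ib][0], d) for (ia, ib), d in found.items()],
        key=lambda t: (t[0].chain_id, t[0].seqnum, t[1].chain_id, t[1].seqnum),
    )


def _charged_reference(res_ref: ResidueRef, atoms) -> np.ndarray | None:
    """Reference point of a charged group; CA fallback for pseudo-atoms.

    Arg: CZ; Lys: NZ; His: NE2; Asp: OD1/OD2 carboxylate midpoint;
    Glu: OE1/OE2 midpoint (CG/CD, then CA, as fallbacks).
    """
    by_name = {a.name: a.position for a in atoms}

    def mid(n1, n2, fallback):
        if n1 in by_name and n2 in by_name:
            return 0.5 * (by_name[n1] + by_name[n2])
        for n in (fallback, "CA"):
            if n in by_name:
                return by_name[n]
        return None

    name = res_ref.name
    if name == "ARG":
        return by_name.get("CZ", by_name.get("CA"))
    if name == "LYS":
        return by_name.get("NZ", by_name.get("CA"))
    if name == "HIS":
        return by_name.get("NE2", by_name.get("CA"))
    if name == "ASP":
        return mid("OD1", "OD2", "CG")
    if name == "GLU":
        return mid("OE1", "OE2", "CD")
    return None


def find_salt_bridges(
    model: StructureModel,
    group_a: Selection,
    group_b: Selection,
    cutoff: float = DEFAULT_SALT_BRIDGE_CUTOFF,
    include_histidine: bool = True,
) -> list[tuple[ResidueRef, ResidueRef, float]]:
    """Basic-acidic residue pairs with charged-group references within ``cutoff``.

    Pairs are reported as (basic residue, acidic residue, distance)
    regardless of which group each belongs to.
    """
    basic = BASIC_RESIDUES if include_histidine else ("ARG", "LYS")
    res_a = _group_residues(model, group_a)
    res_b = _group_residues(model, group_b)
    bridges = []
    for ref_a, _, res_obj_a in res_a:
        for ref_b, _, res_obj_b in res_b:
            if ref_a.name in basic and ref_b.name in ACIDIC_RESIDUES:
                pair = (ref_a, res_obj_a.atoms, ref_b, res_obj_b.atoms)
            elif ref_b.name in basic and ref_a.name in ACIDIC_RESIDUES:
                pair = (ref_b, res_obj_b.atoms, ref_a, res_obj_a.atoms)
            else:
                continue
            basic_ref, basic_atoms, acidic_ref, acidic_atoms = pair
            p = _charged_reference(basic_ref, basic_atoms)
            q = _charged_reference(acidic_ref, acidic_atoms)
            if p is None or q is None:
                continue
            d = float(np.linalg.norm(p - q))
            if d <= cutoff:
                bridges.append((basic_ref, acidic_ref, d))
    return sorted(bridges, key=lambda t: (t[0].chain_id, t[0].seqnum, t[1].seqnum))


def _hydroxyl_reference(res_ref: ResidueRef, atoms) -> np.ndarray:
    by_name = {a.name: a.position for a in atoms}
    for n in ("OG", "OG1", "CA"):
        if n in by_name:
            return by_name[n]
    return atoms[0].position


def phospho_conflict_scan(
    model: StructureModel,
    candidate_sites: Selection,
    partner: Selection,
    cutoff: float = DEFAULT_PHOSPHO_CUTOFF,
    exposure_radius: float = DEFAULT_EXPOSURE_RADIUS,
) -> list[dict]:
    """Classify Ser/Thr phospho-sites against a partner group.

    A site with an acidic partner residue's charged group within ``cutoff``
    of its hydroxyl reference atom is flagged ``repulsive`` (phosphorylation
    is predicted to cause electrostatic repulsion and weaken the contact).
    A site with *no* partner atoms at all within ``exposure_radius`` is
    flagged ``exposed`` (no structural conflict).  Everything else is
    ``buried`` (near the partner but not facing an acidic group).

    Raises
    ------
    ValidationError
        If a candidate residue is not SER or THR.
    """
    sites = _group_residues(model, candidate_sites)
    partners = _group_residues(model, partner)
    partner_coords = np.concatenate([pts for _, pts, _ in partners])
    tree = cKDTree(partner_coords)
    results = []
    for ref, _, res_obj in sites:
        if ref.name not in ("SER", "THR"):
            raise ValidationError(f"phospho-site candidate {ref} is not SER/THR")
        origin = _hydroxyl_reference(ref, res_obj.atoms)
        acidic_near = []
        for pref, _, pres in partners:
            if pref.name not in ACIDIC_RESIDUES:
                continue
            q = _charged_reference(pref, pres.atoms)
            if q is None:
                continue
            d = float(np.linalg.norm(origin - q))
            if d <= cutoff:
                acidic_near.append({"partner": str(pref), "distance": round(d, 3)})
        if acidic_near:
            flag = "repulsive"
        elif not tree.query_ball_point(origin, exposure_radius):
            flag = "exposed"
        else:
            flag = "buried"
        results.append(
            {"site": str(ref), "flag": flag, "acidic_partners": acidic_near}
        )
    return results


def analyze_interface(
    model: StructureModel,
    group_a: Selection,
    group_b: Selection,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    salt_bridge_cutoff: float = DEFAULT_SALT_BRIDGE_CUTOFF,
    phospho_cutoff: float = DEFAULT_PHOSPHO_CUTOFF,
    exposure_radius: float = DEFAULT_EXPOSURE_RADIUS,
) -> InterfaceReport:
    """Full interface report: contacts, salt bridges and phospho-conflicts.

    Ser/Thr residues of ``group_a`` are scanned as candidate phospho-sites
    against ``group_b`` as the partner.
    """
    report = InterfaceReport()
    report.contacts = find_contacts(model, group_a, group_b, contact_cutoff)
    report.salt_bridges = find_salt_bridges(model, group_a, group_b, salt_bridge_cutoff)
    sub_a = select(model, group_a)
    ser_thr = sorted(
        {
            res.seqnum
            for ch in sub_a.chains
            for res in ch.residues
            if res.name in ("SER", "THR")
        }
    )
    if ser_thr:
        candidates = Selection(group_a.chain_id, tuple((n, n) for n in ser_thr))
        report.phospho_conflicts = phospho_conflict_scan(
            model, candidates, group_b, phospho_cutoff, exposure_radius
        )
    return report
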