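"""DASH/Dam1c ring assembly: N-fold expansion, constraint placement, clash checks.

The heterodecamer ring that encircles the kinetochore microtubule is built
by rotational expansion of a single protomer: 17 copies at 360/17 deg
spacing about the tube axis.  The whole ring is then rotated about and
translated along the axis so that residue-proximity constraints — the
juxtaposition of Spc34 Thr199 with Ndc80 residue 583 and the Spc19/Nuf2
contact that define "interaction C" — are satisfied, subject to a steric
clash check against the docked Ndc80c and the microtubule wall.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.spatial import cKDTree

from .errors import InvalidArgumentError, SelectionError
from .geometry import RigidTransform, axis_rotation
from .structures import Selection, StructureModel, merge, select

__all__ = [
    "RingSpec",
    "ConstraintPair",
    "ClashReport",
    "expand_ring",
    "constraint_score",
    "place_ring",
    "detect_clashes",
]

_Z = np.array([0.0, 0.0, 1.0])

#: Hard-sphere heavy-atom overlap threshold (A); conventional default.
DEFAULT_CLASH_CUTOFF = 2.4


@dataclass(frozen=True)
class RingSpec:
    """N-fold ring description around ``axis`` with rigid (phi, z) placement.

    n_fold : number of protomer copies (17 for the DASH/Dam1c ring)
    axis : tube axis direction (through the origin)
    ring_radius : A, protomer reference distance from the axis
    phi : deg, whole-ring rotation about the axis
    z : A, whole-ring translation along the axis
    """

    n_fold: int = 17
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    ring_radius: float = 160.0
    phi: float = 0.0
    z: float = 0.0

    def __post_init__(self):
        if self.n_fold < 1:
            raise InvalidArgumentError("n_fold must be >= 1")
        if np.linalg.norm(self.axis) < 1e-12:
            raise InvalidArgumentError("ring axis must be non-zero")

    def ring_motion(self) -> RigidTransform:
        """The rigid (phi, z) motion applied to the whole ring."""
        axis = np.asarray(self.axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        rot = axis_rotation(axis, self.phi)
        return RigidTransform(rot.rotation, rot.translation + self.z * axis)


@dataclass(frozen=True)
class ConstraintPair:
    """Residue-proximity constraint between two single-residue selections."""

    selection_a: Selection
    selection_b: Selection
    target_distance: float = 10.0
    weight: float = 1.0

    def __post_init__(self):
        if self.target_distance <= 0:
            raise InvalidArgumentError("target_distance must be positive")


@dataclass
class ClashReport:
    """Atom pairs of two models closer than a hard-sphere cutoff."""

    pairs: list[tuple[str, str, float]] = field(default_factory=list)
    cutoff: float = DEFAULT_CLASH_CUTOFF

    @property
    def count(self) -> int:
        return len(self.pairs)


def _copy_chain_id(orig: str, k: int) -> str:
    return f"{orig}.c{k:02d}"


def expand_ring(protomer: StructureModel, spec: RingSpec) -> StructureModel:
    """Rotationally expand a placed protomer into the closed N-fold ring.

    Copy k is the protomer rotated by ``k * 360/n_fold`` about the axis,
    after which the whole ring receives the (phi, z) motion.  Chain ids
    gain a deterministic ``.cKK`` copy suffix.
    """
    axis = np.asarray(spec.axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    motion = spec.ring_motion()
    copies = []
    step = 360.0 / spec.n_fold
    for k in range(spec.n_fold):
        t = motion.compose(axis_rotation(axis, k * step))
        copy = protomer.transformed(t)
        copy.metadata = {}
        for ch in copy.chains:
            ch.chain_id = _copy_chain_id(ch.chain_id, k)
        copies.append(copy)
    ring = merge(copies, chain_relabel_policy="strict")
    ring.metadata = {
        "title": f"{spec.n_fold}-fold ring",
        "ring_spec": spec,
        "protomer_chains": [c.chain_id for c in protomer.chains],
    }
    return ring


def _constraint_points(model: StructureModel, sel: Selection) -> np.ndarray:
    sub = select(model, sel)
    pts = [a.position for _, _, a in sub.iter_atoms()]
    if not pts:
        raise SelectionError(
            f"constraint selection {sel.chain_id}:{sel.ranges} resolves to no atoms"
        )
    return np.stack(pts)


def constraint_score(model: StructureModel, constraints) -> float:
    """Weighted squared deviation of minimum inter-selection distances.

    ``sum_i w_i * (min_dist_i - target_i)**2`` over the constraint list;
    zero iff every constraint is met exactly.
    """
    total = 0.0
    for c in constraints:
        pa = _constraint_points(model, c.selection_a)
        pb = _constraint_points(model, c.selection_b)
        d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2)).min()
        total += c.weight * (d - c.target_distance) ** 2
    return float(total)


def detect_clashes(
    model_a: StructureModel, model_b: StructureModel, cutoff: float = DEFAULT_CLASH_CUTOFF
) -> ClashReport:
    """All inter-model atom pairs closer than ``cutoff``, via a KD-tree.

    Equivalent to the exhaustive pairwise comparison; atom labels are
    ``chain/resnum/atomname``.  Symmetric in its arguments up to pair order.
    """
    if cutoff <= 0:
        raise InvalidArgumentError("clash cutoff must be positive")
    labels_a, labels_b = [], []
    for ch, res, atom in model_a.iter_atoms():
        labels_a.append(f"{ch.chain_id}/{res.seqnum}/{atom.name}")
    for ch, res, atom in model_b.iter_atoms():
        labels_b.append(f"{ch.chain_id}/{res.seqnum}/{atom.name}")
    ca, cb = model_a.coords(), model_b.coords()
    report = ClashReport(cutoff=cutoff)
    if len(ca) == 0 or len(cb) == 0:
        return report
    tree_a, tree_b = cKDTree(ca), cKDTree(cb)
    for ia, neighbors in enumerate(tree_a.query_ball_tree(tree_b, cutoff)):
        for ib in neighbors:
            d = float(np.linalg.norm(ca[ia] - cb[ib]))
            if d < cutoff:
                report.pairs.append((labels_a[ia], labels_b[ib], d))
    report.pairs.sort()
    return report


def _ring_objective(protomer, constraints, counterpart_points):
    """Pre-resolve constraint atoms so (phi, z) evaluation is cheap.

    Returns ``(score, score_row)``: a scalar objective at one (phi, z) and
    a vectorized evaluation over a whole z column at fixed phi, used by the
    grid search.
    """
    own_points = [_constraint_points(protomer, c.selection_a) for c in constraints]
    weights = [c.weight for c in constraints]
    targets = [c.target_distance for c in constraints]

    def score_row(phi: float, zs: np.ndarray) -> np.ndarray:
        rot = axis_rotation(_Z, phi)
        total = np.zeros(len(zs))
        for pa, pb, w, tgt in zip(own_points, counterpart_points, weights, targets):
            moved = rot.apply(pa)  # (n, 3)
            dxy2 = (
                (moved[:, None, 0] - pb[None, :, 0]) ** 2
                + (moved[:, None, 1] - pb[None, :, 1]) ** 2
            )  # (n, m)
            dz0 = moved[:, None, 2] - pb[None, :, 2]  # (n, m)
            d2 = dxy2[None, :, :] + (dz0[None, :, :] + zs[:, None, None]) ** 2
            d = np.sqrt(d2.reshape(len(zs), -1).min(axis=1))
            total += w * (d - tgt) ** 2
        return total

    def score(phi: float, z: float) -> float:
        return float(score_row(phi, np.array([z]))[0])

    return score, score_row


def place_ring(
    protomer: StructureModel,
    spec_template: RingSpec,
    docked_ndc80c: StructureModel,
    constraints,
    mt: StructureModel | None = None,
    phi_step: float = 0.5,
    z_step: float = 0.5,
    z_range: tuple[float, float] = (-60.0, 60.0),
    clash_cutoff: float = DEFAULT_CLASH_CUTOFF,
) -> tuple[RingSpec, StructureModel, ClashReport]:
    """Find the (phi, z) ring placement satisfying the proximity constraints.

    A deterministic grid search (phi over [0, 360) at ``phi_step`` <= 0.5
    deg, z over ``z_range`` at ``z_step`` <= 0.5 A) is followed by local
    Nelder-Mead refinement.  Ties on the grid resolve to the
    lexicographically smallest (phi, z).  Only the constraint-bearing
    protomer copy (copy 0) is scored against the single docked Ndc80c.
    Returns the optimal RingSpec, the assembled ring, and a clash report of
    the ring against Ndc80c (and the microtubule, when given).
    """
    constraints = list(constraints)
    if not constraints:
        raise InvalidArgumentError("place_ring requires at least one constraint")
    if phi_step <= 0 or phi_step > 0.5 or z_step <= 0 or z_step > 0.5:
        raise InvalidArgumentError("grid steps must be in (0, 0.5]")
    counterpart = [_constraint_points(docked_ndc80c, c.selection_b) for c in constraints]
    score, score_row = _ring_objective(protomer, constraints, counterpart)

    # ascending scan with strict improvement keeps the lexicographically
    # smallest (phi, z) among exact ties
    best_s, phi0, z0 = np.inf, 0.0, 0.0
    phis = np.arange(0.0, 360.0, phi_step)
    zs = np.arange(z_range[0], z_range[1] + 0.5 * z_step, z_step)
    for phi in phis:
        row = score_row(float(phi), zs)
        i = int(np.argmin(row))  # first occurrence -> smallest z
        if row[i] < best_s:
            best_s, phi0, z0 = float(row[i]), float(phi), float(zs[i])

    res = optimize.minimize(
        lambda x: score(x[0], x[1]),
        x0=np.array([phi0, z0]),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 500},
    )
    if res.fun < best_s:
        phi_star, z_star = float(res.x[0]) % 360.0, float(res.x[1])
    else:
        phi_star, z_star = phi0, z0

    placed_spec = RingSpec(
        n_fold=spec_template.n_fold,
        axis=spec_template.axis,
        ring_radius=spec_template.ring_radius,
        phi=phi_star,
        z=z_star,
    )
    ring = expand_ring(protomer, placed_spec)
    environment = [docked_ndc80c] if mt is None else [docked_ndc80c, mt]
    env = merge([m.copy() for m in environment], chain_relabel_policy="suffix")
    report = detect_clashes(ring, env, cutoff=clash_cutoff)
    ring.metadata["constraint_score"] = score(phi_star, z_star)
    return placed_spec, ring, report
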