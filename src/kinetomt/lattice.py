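"""Helical microtubule lattice: generation, plus-end flaring, parameter estimation.

A microtubule is modelled as ``n_pf`` protofilaments of tubulin dimers on a
helical lattice.  The tube axis is +z and the plus end points toward +z.
Four parameters relate neighbouring dimers (yeast values from cryo-EM of
GTP-polymerized tubulin):

* ``rise_dimer`` = 83.3 A and ``twist_dimer`` = 0.43 deg between consecutive
  dimers within one protofilament;
* ``rise_pf`` = 9.65 A and ``twist_pf`` = -27.6 deg between adjacent
  protofilaments.

The sign of ``twist_pf`` follows the right-hand rule about +z (negative =
clockwise viewed from the plus end).  ``round(360 / |twist_pf|)`` gives the
protofilament count that closes the tube: 13 for the default parameters.

Plus-end "ram's horn" flaring is modelled by bending each dimer beyond a
start index outward in its protofilament's radial-axial plane, hinging at
the previous dimer's distal end, with a constant per-dimer bend increment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (
    ConfigurationError,
    InsufficientDataError,
    InvalidArgumentError,
)
from .geometry import RigidTransform, axis_rotation
from .structures import StructureModel, merge

__all__ = [
    "LatticeParams",
    "FlareProfile",
    "lattice_transform",
    "build_straight_mt",
    "closure_count",
    "flare_protofilaments",
    "estimate_lattice_params",
    "YEAST_MT_PARAMS",
]

_Z = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class LatticeParams:
    """Helical lattice parameters of an N-protofilament microtubule.

    rise_dimer : A, axial rise between consecutive dimers in one protofilament
    twist_dimer : deg, rotation between consecutive dimers in one protofilament
    rise_pf : A, axial rise between adjacent protofilaments
    twist_pf : deg, signed rotation between adjacent protofilaments
    n_pf : protofilament count
    radius : A, distance of the dimer reference frame from the tube axis
    """

    rise_dimer: float = 83.3
    twist_dimer: float = 0.43
    rise_pf: float = 9.65
    twist_pf: float = -27.6
    n_pf: int = 13
    radius: float = 105.0

    def __post_init__(self):
        if self.rise_dimer <= 0:
            raise InvalidArgumentError("rise_dimer must be positive")
        if self.n_pf < 1:
            raise InvalidArgumentError("n_pf must be >= 1")
        if self.radius <= 0:
            raise InvalidArgumentError("radius must be positive")
        if self.n_pf > 1 and abs(self.twist_pf) <= 0:
            raise InvalidArgumentError("twist_pf must be non-zero for multi-pf lattices")


#: Published yeast lattice parameters (13-protofilament tube).
YEAST_MT_PARAMS = LatticeParams()


@dataclass(frozen=True)
class FlareProfile:
    """Outward plus-end curl: constant bend increment from a start index.

    flare_start : 0-based dimer index (along the protofilament, minus to
        plus end) of the first bent dimer.
    per_dimer_bend : deg of additional outward rotation per flared dimer;
        the k-th flared dimer ends up at k * per_dimer_bend to the tube axis.
    bend_plane : only "radial_axial" is defined — each protofilament curls
        outward in its own radial-axial plane.
    """

    flare_start: int = 0
    per_dimer_bend: float = 22.0
    bend_plane: str = "radial_axial"

    def __post_init__(self):
        if self.per_dimer_bend < 0:
            raise InvalidArgumentError("per_dimer_bend must be >= 0")
        if self.flare_start < 0:
            raise InvalidArgumentError("flare_start must be >= 0")
        if self.bend_plane != "radial_axial":
            raise InvalidArgumentError(f"unknown bend plane {self.bend_plane!r}")


def lattice_transform(params: LatticeParams, pf_index: int, dimer_index: int) -> RigidTransform:
    """Helical symmetry operator placing the template at site (pf, dimer).

    Rotation about +z by ``pf*twist_pf + dimer*twist_dimer`` and axial
    translation ``pf*rise_pf + dimer*rise_dimer``; site (0, 0) is the
    identity.
    """
    if not 0 <= pf_index < params.n_pf:
        raise InvalidArgumentError(
            f"pf_index {pf_index} outside [0, {params.n_pf})"
        )
    if dimer_index < 0:
        raise InvalidArgumentError("dimer_index must be >= 0")
    angle = pf_index * params.twist_pf + dimer_index * params.twist_dimer
    shift = pf_index * params.rise_pf + dimer_index * params.rise_dimer
    rot = axis_rotation(_Z, angle)
    return RigidTransform(rot.rotation, rot.translation + shift * _Z)


def closure_count(twist_pf: float) -> int:
    """Protofilament count closing the tube: nearest integer to 360/|twist|."""
    if twist_pf == 0:
        raise InvalidArgumentError("twist_pf must be non-zero")
    return int(round(360.0 / abs(twist_pf)))


def _template_placement(template: StructureModel, params: LatticeParams) -> RigidTransform:
    """Transform taking the template from its body frame to lattice site (0,0).

    The body frame annotation is ``metadata["body_frame"] = (origin, axes)``
    with ``axes`` a 3x3 rotation whose columns are the frame's x/y/z in the
    template's coordinates.  The placed frame sits at (radius, 0, 0) with
    its axes aligned to the lab axes (z = tube axis, x = outward radial).
    """
    frame = template.metadata.get("body_frame")
    if frame is None:
        raise ConfigurationError(
            "template dimer lacks a body frame annotation "
            "(metadata['body_frame'] = (origin, 3x3 axes))"
        )
    origin, axes = frame
    origin = np.asarray(origin, dtype=float).reshape(3)
    axes = np.asarray(axes, dtype=float).reshape(3, 3)
    frame_to_lab = RigidTransform(axes, origin).inverse()
    return RigidTransform.from_translation([params.radius, 0.0, 0.0]).compose(frame_to_lab)


def _site_chain_id(orig: str, pf: int, dimer: int) -> str:
    return f"{orig}.p{pf:02d}d{dimer:02d}"


def build_straight_mt(
    template_dimer: StructureModel,
    params: LatticeParams,
    n_dimers_per_pf: int,
) -> StructureModel:
    """Replicate a tubulin-dimer template over the straight helical lattice.

    Chain ids encode the lattice site (``<orig>.pPPdDD``) so downstream
    operations (flaring, estimation) can recover (pf, dimer) indices; the
    same indices are kept in ``metadata["lattice_sites"]``.
    """
    if n_dimers_per_pf < 1:
        raise InvalidArgumentError("n_dimers_per_pf must be >= 1")
    place = _template_placement(template_dimer, params)
    copies = []
    sites = {}
    for p in range(params.n_pf):
        for d in range(n_dimers_per_pf):
            t = lattice_transform(params, p, d).compose(place)
            copy = template_dimer.transformed(t)
            copy.metadata = {}
            for ch in copy.chains:
                new_id = _site_chain_id(ch.chain_id, p, d)
                sites[new_id] = (p, d)
                ch.chain_id = new_id
            copies.append(copy)
    mt = merge(copies, chain_relabel_policy="strict")
    mt.metadata = {
        "title": f"straight {params.n_pf}-pf microtubule",
        "lattice_params": params,
        "lattice_sites": sites,
        "n_dimers_per_pf": n_dimers_per_pf,
    }
    return mt


def _dimer_groups(mt: StructureModel) -> dict[tuple[int, int], list]:
    """Group chains by lattice site using metadata or parseable chain ids."""
    sites = mt.metadata.get("lattice_sites")
    groups: dict[tuple[int, int], list] = {}
    for ch in mt.chains:
        if sites and ch.chain_id in sites:
            key = tuple(sites[ch.chain_id])
        else:
            base, sep, tag = ch.chain_id.rpartition(".")
            if not sep or len(tag) != 6 or tag[0] != "p" or tag[3] != "d":
                raise ConfigurationError(
                    f"chain {ch.chain_id!r}: lattice site not recoverable"
                )
            key = (int(tag[1:3]), int(tag[4:6]))
        groups.setdefault(key, []).append(ch)
    return groups


def _group_coords(chains) -> np.ndarray:
    return np.concatenate(
        [np.stack([a.position for r in ch.residues for a in r.atoms]) for ch in chains]
    )


def flare_protofilaments(
    mt: StructureModel, profile: FlareProfile, params: LatticeParams
) -> StructureModel:
    """Curl protofilament plus ends outward ("ram's horn" geometry).

    Dimers with index < ``flare_start`` are untouched.  The k-th flared
    dimer (k = 1 at ``flare_start``) is rotated by an additional
    ``per_dimer_bend`` about the tangential axis through the hinge point at
    the previous dimer's distal (+z) end, accumulating to
    ``k * per_dimer_bend`` relative to the tube axis.  Intra-dimer geometry
    stays rigid and hinge continuity preserves inter-dimer spacing.
    """
    out = mt.copy()
    groups = _dimer_groups(out)
    n_dimers = 1 + max(d for _, d in groups)
    if profile.flare_start >= n_dimers:
        warnings.warn(
            f"flare_start {profile.flare_start} beyond protofilament length "
            f"{n_dimers}; returning input unchanged",
            stacklevel=2,
        )
        return out
    if profile.per_dimer_bend == 0:
        return out

    pfs = sorted({p for p, _ in groups})
    for p in pfs:
        if profile.flare_start > 0:
            prev_centroid = _group_coords(groups[(p, profile.flare_start - 1)]).mean(axis=0)
            prev_top = prev_centroid + (params.rise_dimer / 2.0) * _Z
            plane_ref = prev_centroid
        else:
            # no preceding dimer: hinge at the first dimer's proximal base
            first_centroid = _group_coords(groups[(p, 0)]).mean(axis=0)
            prev_top = first_centroid - (params.rise_dimer / 2.0) * _Z
            plane_ref = first_centroid
        # bend plane fixed per protofilament: radial direction at the hinge dimer
        radial = np.array([plane_ref[0], plane_ref[1], 0.0])
        radial /= np.linalg.norm(radial)
        tangent = np.cross(_Z, radial)  # +bend about this axis tips +z toward +radial

        accumulated = RigidTransform.identity()
        for d in range(profile.flare_start, n_dimers):
            chains = groups.get((p, d))
            if chains is None:
                continue
            hinge = accumulated.apply(prev_top)
            step = axis_rotation(tangent, profile.per_dimer_bend, hinge)
            accumulated = step.compose(accumulated)
            coords = _group_coords(chains)
            new_coords = accumulated.apply(coords)
            i = 0
            for ch in chains:
                for res in ch.residues:
                    for atom in res.atoms:
                        atom.position = new_coords[i]
                        i += 1
            prev_top = coords.mean(axis=0) + (params.rise_dimer / 2.0) * _Z
    out.metadata["flare_profile"] = profile
    return out


def estimate_lattice_params(mt: StructureModel) -> LatticeParams:
    """Re-estimate helical parameters from dimer centroids of a straight lattice.

    Averages axial offsets and azimuthal increments over all consecutive
    dimer pairs (within protofilaments) and all adjacent protofilament
    pairs (at equal dimer index); the tube axis is assumed to be +z, as
    produced by :func:`build_straight_mt`.  On a noiseless generated
    lattice each estimate reproduces the generating value to ~1e-6.
    """
    groups = _dimer_groups(mt)
    centroids = {site: _group_coords(chs).mean(axis=0) for site, chs in groups.items()}
    pfs = sorted({p for p, _ in centroids})
    dimers = sorted({d for _, d in centroids})
    if len(dimers) < 2:
        raise InsufficientDataError("need >= 2 dimers per protofilament")

    def azimuth(c):
        return np.arctan2(c[1], c[0])

    rises_d, twists_d = [], []
    for p in pfs:
        for d1, d2 in zip(dimers, dimers[1:]):
            a, b = centroids.get((p, d1)), centroids.get((p, d2))
            if a is None or b is None:
                continue
            rises_d.append(b[2] - a[2])
            dphi = np.rad2deg(azimuth(b) - azimuth(a))
            twists_d.append((dphi + 180.0) % 360.0 - 180.0)
    if not rises_d:
        raise InsufficientDataError("no consecutive dimer pairs found")

    radius = float(np.mean([np.hypot(c[0], c[1]) for c in centroids.values()]))
    rise_dimer = float(np.mean(rises_d))
    twist_dimer = float(np.mean(twists_d))

    if len(pfs) < 2:
        warnings.warn("single protofilament: inter-pf parameters unavailable", stacklevel=2)
        return LatticeParams(
            rise_dimer=rise_dimer,
            twist_dimer=twist_dimer,
            rise_pf=float("nan"),
            twist_pf=float("nan"),
            n_pf=1,
            radius=radius,
        )

    rises_p, twists_p = [], []
    for p1, p2 in zip(pfs, pfs[1:]):
        for d in dimers:
            a, b = centroids.get((p1, d)), centroids.get((p2, d))
            if a is None or b is None:
                continue
            rises_p.append(b[2] - a[2])
            dphi = np.rad2deg(azimuth(b) - azimuth(a))
            twists_p.append((dphi + 180.0) % 360.0 - 180.0)
    return LatticeParams(
        rise_dimer=rise_dimer,
        twist_dimer=twist_dimer,
        rise_pf=float(np.mean(rises_p)),
        twist_pf=float(np.mean(twists_p)),
        n_pf=len(pfs),
        radius=radius,
    )
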