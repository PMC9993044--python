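"""Synthetic coarse-grained fixtures for every pipeline stage.

All generators emit one CA-named pseudo-atom (element ``X``) per residue,
with *S. cerevisiae* residue numbering at the landmark positions so that
selections in tests and docs read like the biology (``Dam1:252-270``,
``Spc34:199``).  Landmark geometry is deterministic — only decorative
cluster beads receive seeded jitter — so the calibrated distances hold for
any seed:

* pseudo-tubulin dimer: two lobes (alpha/beta), 80 A long along its axis,
  with an annotated body frame;
* Ndc80c rod: a two-segment hinged rod, head tip to Spc24:Spc25 end 600 A,
  hinge (Ndc80 412 / Nuf2 245) at 160 A, loop at 240 A from the head;
* DASH/Dam1c protomer: ten chains forming a wedge of angular width 360/17
  deg at the ring radius, with the Spc34 Thr199 protrusion and the Dam1
  C-terminal arm (residues 252-305);
* toy interface: the Dam1:Ndc80 contact pattern — Ser257 opposite Glu276,
  the Arg299-Asp295 salt bridge, Ser292 isolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .docking import HingedRod
from .errors import InvalidArgumentError
from .structures import Atom, Chain, Residue, Selection, StructureModel

__all__ = [
    "FixtureSpec",
    "make_pseudo_tubulin",
    "make_ndc80c_rod",
    "make_dash_protomer",
    "make_toy_interface",
    "make_fixture",
    "measure_rod_landmarks",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 20230308

_KINDS = ("pseudo_tubulin", "ndc80c_rod", "dash_protomer", "toy_interface")


@dataclass(frozen=True)
class FixtureSpec:
    """What to generate and with which geometry overrides."""

    kind: str = "pseudo_tubulin"
    seed: int = DEFAULT_SEED
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise InvalidArgumentError(f"unknown fixture kind {self.kind!r}")

    def get(self, key, default):
        return self.overrides.get(key, default)


def _bead(position, name="CA", element="X") -> Atom:
    return Atom(name, element, np.asarray(position, dtype=float))


def _residues(entries) -> list[Residue]:
    """entries: iterable of (seqnum, resname, position)."""
    return [Residue(num, name, [_bead(pos)]) for num, name, pos in entries]


# -- pseudo-tubulin ------------------------------------------------------------


def make_pseudo_tubulin(spec: FixtureSpec | None = None) -> StructureModel:
    """Two-lobed bead dimer (alpha + beta chains), 80 A along +z.

    The body frame (origin at the dimer centroid, axes = lab axes, z = the
    dimer's long axis) is annotated in ``metadata["body_frame"]`` for the
    lattice builder.
    """
    spec = spec or FixtureSpec("pseudo_tubulin")
    rng = np.random.default_rng(spec.seed)
    length = spec.get("length", 80.0)
    lobe_radius = spec.get("lobe_radius", 10.0)
    jitter = spec.get("jitter", 0.3)

    def lobe(z_lo, z_hi, start_res):
        entries = []
        num = start_res
        for z in np.linspace(z_lo, z_hi, 5):
            for k in range(6):
                phi = 2 * np.pi * k / 6
                x = lobe_radius * np.cos(phi) + rng.normal(0.0, jitter)
                y = lobe_radius * np.sin(phi) + rng.normal(0.0, jitter)
                entries.append((num, "ALA", (x, y, z)))
                num += 1
        return entries

    half = length / 2.0
    alpha = Chain("A", _residues(lobe(-half, -2.0, 1)))
    beta = Chain("B", _residues(lobe(2.0, half, 1)))
    model = StructureModel([alpha, beta], {"title": "synthetic pseudo-tubulin dimer"})
    model.metadata["body_frame"] = (model.centroid(), np.eye(3))
    return model


# -- Ndc80c rod ----------------------------------------------------------------

_ROD_LANDMARKS = {
    "head": ("Ndc80", 114),
    "hinge": ("Ndc80", 412),
    "loop": ("Ndc80", 490),
    "end": ("Spc24", 213),
}


def _line_beads(resnums, z_lo, z_hi, x_off, resname="ALA", names=None):
    zs = np.linspace(z_lo, z_hi, len(resnums))
    names = names or {}
    return [
        (num, names.get(num, resname), (x_off, 0.0, z)) for num, z in zip(resnums, zs)
    ]


def _cluster_beads(resnums, center, radius, rng, resname="ALA"):
    out = []
    for num in resnums:
        offset = rng.normal(0.0, radius / 2.0, size=3)
        out.append((num, resname, np.asarray(center) + offset))
    return out


def make_ndc80c_rod(spec: FixtureSpec | None = None) -> HingedRod:
    """Calibrated two-segment Ndc80c stand-in along +z.

    Segment A: the Ndc80:Nuf2 globular head (tip at z = 0) and the
    head-proximal coiled-coil up to the hinge residues (Ndc80 412 / Nuf2
    245) at z = 160.  Glu276 and Asp295 pseudo-residues sit at the head
    base for interface fixtures.

    Segment B: the hinge-distal shaft carrying the loop landmark (Ndc80
    490) at z = 240 and the interaction-C landmark (Ndc80 583), ending in
    Spc24/Spc25 clusters whose terminal landmark (Spc24 213) lies at
    z = 600.
    """
    spec = spec or FixtureSpec("ndc80c_rod")
    rng = np.random.default_rng(spec.seed)
    xo = spec.get("pair_offset", 1.2)  # lateral half-spacing of the coiled-coil

    # --- segment A: head + proximal coil, z in [0, 160]
    ndc80_a = [(114, "ALA", (xo, 0.0, 0.0))]  # head tip landmark, jitter-free
    ndc80_a += _cluster_beads(range(120, 136), (xo, 0.0, 12.0), 8.0, rng)
    ndc80_a += [(276, "GLU", (xo, 2.0, 24.0)), (295, "ASP", (xo, -2.0, 28.0))]
    ndc80_a += _line_beads(list(range(300, 413, 8)), 36.0, 160.0, xo)

    nuf2_a = [(1, "ALA", (-xo, 0.0, 0.0))]
    nuf2_a += _cluster_beads(range(5, 21), (-xo, 0.0, 12.0), 8.0, rng)
    nuf2_a += _line_beads(list(range(65, 246, 15)), 30.0, 160.0, -xo)

    segment_a = StructureModel(
        [Chain("Ndc80", _residues(ndc80_a)), Chain("Nuf2", _residues(nuf2_a))],
        {"title": "synthetic Ndc80c rod, head-proximal segment"},
    )

    # --- segment B: distal shaft + Spc24:Spc25 end, z in (160, 600]
    ndc80_b = _line_beads(list(range(413, 491, 7)), 161.0, 240.0, xo)
    ndc80_b += _line_beads(list(range(511, 680, 24)), 262.0, 545.0, xo)  # includes 583
    ndc80_b += [(691, "ALA", (xo, 0.0, 560.0))]

    nuf2_b = [(246, "ALA", (-xo, 0.0, 161.0))]
    nuf2_b += _line_beads(list(range(260, 441, 20)), 170.0, 550.0, -xo)
    nuf2_b += [(451, "ALA", (-xo, 0.0, 560.0))]

    spc24 = _cluster_beads(range(155, 213, 8), (2.0, 2.0, 580.0), 6.0, rng)
    spc24 += [(213, "ALA", (0.0, 0.0, 600.0))]  # far-end landmark, jitter-free
    spc25 = _cluster_beads(range(160, 222, 8), (-2.0, -2.0, 582.0), 6.0, rng)

    segment_b = StructureModel(
        [
            Chain("Ndc80", _residues(ndc80_b)),
            Chain("Nuf2", _residues(nuf2_b)),
            Chain("Spc24", _residues(spc24)),
            Chain("Spc25", _residues(spc25)),
        ],
        {"title": "synthetic Ndc80c rod, hinge-distal segment"},
    )
    for seg in (segment_a, segment_b):
        seg.metadata["landmarks"] = dict(_ROD_LANDMARKS)

    return HingedRod(
        segment_a=segment_a,
        segment_b=segment_b,
        hinge_a=[Selection("Ndc80", ((412, 412),)), Selection("Nuf2", ((245, 245),))],
        hinge_b=[Selection("Ndc80", ((413, 413),)), Selection("Nuf2", ((246, 246),))],
    )


def measure_rod_landmarks(model: StructureModel) -> dict[str, float]:
    """Landmark distances of a (straightened) rod model, in Angstrom.

    Locates the landmark beads recorded in ``metadata["landmarks"]`` and
    returns head-to-hinge, head-to-loop and end-to-end distances.
    """
    landmarks = model.metadata.get("landmarks", _ROD_LANDMARKS)
    points = {}
    for key, (chain_id, seqnum) in landmarks.items():
        chain = model.chain(chain_id)
        res = chain.residue(seqnum) if chain else None
        if res is None:
            raise InvalidArgumentError(f"landmark {key}: {chain_id} {seqnum} not in model")
        points[key] = res.atoms[0].position
    return {
        "head_to_hinge": float(np.linalg.norm(points["hinge"] - points["head"])),
        "head_to_loop": float(np.linalg.norm(points["loop"] - points["head"])),
        "end_to_end": float(np.linalg.norm(points["end"] - points["head"])),
    }


# -- DASH/Dam1c protomer -------------------------------------------------------

_PROTOMER_CORE = {
    # chain -> residue range of the well-ordered core
    "Ask1": (2, 69),
    "Dad1": (14, 73),
    "Dad2": (2, 85),
    "Dad3": (6, 94),
    "Dad4": (2, 72),
    "Dam1": (54, 162),
    "Duo1": (61, 180),
    "Hsk3": (2, 69),
    "Spc19": (2, 106),
    "Spc34": (2, 118),
}


def make_dash_protomer(spec: FixtureSpec | None = None) -> StructureModel:
    """Ten-chain wedge protomer of the DASH/Dam1c heterodecamer.

    The wedge spans exactly 360/17 deg of azimuth at the ring radius (so 17
    copies close the ring), centred on azimuth 0 at ``ring_radius`` from
    the tube axis.  The Spc34 chain carries Thr199 at the tip of an
    outward protrusion (with Spc19 residues 128-165 alongside), and the
    Dam1 chain carries its C-terminal arm, residues 252-305 one bead per
    residue, with Ser257/265/292 and Arg299 named.
    """
    spec = spec or FixtureSpec("dash_protomer")
    rng = np.random.default_rng(spec.seed)
    R = spec.get("ring_radius", 160.0)
    n_fold = spec.get("n_fold", 17)
    half_width = 180.0 / n_fold  # deg; total width 360/n_fold

    def at(az_deg, radius, z):
        a = np.deg2rad(az_deg)
        return (radius * np.cos(a), radius * np.sin(a), z)

    chains = []
    names = sorted(_PROTOMER_CORE)
    for i, cname in enumerate(names):
        lo, hi = _PROTOMER_CORE[cname]
        az = -half_width + (2.0 * half_width) * i / (len(names) - 1)
        resnums = np.linspace(lo, hi, 6).round().astype(int)
        resnums = np.unique(resnums)
        entries = []
        for j, num in enumerate(resnums):
            radius = R + rng.normal(0.0, 2.0)
            z = -10.0 + 20.0 * j / (len(resnums) - 1)
            entries.append((int(num), "ALA", at(az, radius, z)))
        chains.append(Chain(cname, _residues(entries)))

    model = StructureModel(chains, {"title": "synthetic DASH/Dam1c protomer"})

    # Spc34 protrusion: residues 157-264 reaching outward, Thr199 at the tip
    spc34 = model.chain("Spc34")
    prot_nums = [157, 171, 185, 199, 213, 235, 264]
    prot_radii = [R + 12, R + 24, R + 36, R + 48, R + 36, R + 24, R + 12]
    for num, radius in zip(prot_nums, prot_radii):
        name = "THR" if num == 199 else "ALA"
        spc34.residues.append(Residue(num, name, [_bead(at(0.0, radius, 6.0))]))
    spc34.residues.sort(key=lambda r: r.seqnum)
    spc34.validate()

    # Spc19 protrusion companion: residues 128-165 next to the Spc34 tip
    spc19 = model.chain("Spc19")
    for k, num in enumerate(range(128, 166, 6)):
        spc19.residues.append(
            Residue(num, "ALA", [_bead(at(1.5, R + 14 + 5 * k, 2.0))])
        )
    spc19.residues.sort(key=lambda r: r.seqnum)
    spc19.validate()

    # Dam1 C-terminal arm: one bead per residue 252-305, trailing in -z
    dam1 = model.chain("Dam1")
    ser_arg = {257: "SER", 265: "SER", 292: "SER", 299: "ARG"}
    for k, num in enumerate(range(252, 306)):
        pos = at(-1.0, R - 6.0, -14.0 - 1.0 * k)
        dam1.residues.append(Residue(num, ser_arg.get(num, "ALA"), [_bead(pos)]))
    dam1.residues.sort(key=lambda r: r.seqnum)
    dam1.validate()

    model.metadata["ring_radius"] = R
    model.metadata["n_fold"] = n_fold
    return model


# -- toy interface -------------------------------------------------------------


def make_toy_interface(spec: FixtureSpec | None = None) -> StructureModel:
    """Two-chain fixture with the Dam1:Ndc80 head contact pattern.

    By construction: Ser257 sits 4 A from Glu276 (phospho-conflict),
    Arg299 3 A from Asp295 (the salt bridge), and Ser292 more than 8 A
    from every partner atom (exposed).  Coordinates are deterministic;
    the seed only shuffles nothing here but keeps the FixtureSpec uniform.
    """
    spec = spec or FixtureSpec("toy_interface")
    dam1 = Chain(
        "Dam1",
        _residues(
            [
                (257, "SER", (0.0, 0.0, 0.0)),
                (265, "SER", (10.0, 0.0, 0.0)),
                (292, "SER", (30.0, 0.0, 0.0)),
                (299, "ARG", (20.0, 0.0, 0.0)),
            ]
        ),
    )
    ndc80 = Chain(
        "Ndc80",
        _residues(
            [
                (276, "GLU", (0.0, 4.0, 0.0)),
                (295, "ASP", (20.0, 3.0, 0.0)),
            ]
        ),
    )
    return StructureModel([dam1, ndc80], {"title": "synthetic Dam1:Ndc80 toy interface"})


def make_fixture(spec: FixtureSpec):
    """Dispatch on ``spec.kind``; the rod returns a HingedRod, others a model."""
    return {
        "pseudo_tubulin": make_pseudo_tubulin,
        "ndc80c_rod": make_ndc80c_rod,
        "dash_protomer": make_dash_protomer,
        "toy_interface": make_toy_interface,
    }[spec.kind](spec)
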