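"""Hierarchical coordinate container with PDB/mmCIF I/O and residue-range selection.

The in-memory model is a plain chain -> residue -> atom hierarchy carrying
numpy positions; file reading and writing are delegated to gemmi.  Chains may
carry multi-character ids (fixture chains are named after their subunits,
e.g. ``Ndc80`` or ``Spc34``), which mmCIF preserves exactly.  PDB output
relabels such chains deterministically (A-Z, a-z, 0-9) and splits assemblies
of more than 62 chains across MODEL records; ``write_structure`` returns the
chain-id map so callers can invert the relabelling.

Selections use the string form ``chain:start-end[,start-end...][@atomname]``
with 1-based, inclusive residue ranges — the same convention used for
construct definitions such as ``Dam1:252-270,290-305``.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import gemmi

from .errors import (
    ChainCollisionError,
    InvalidArgumentError,
    ParseError,
    SelectionError,
)
from .geometry import RigidTransform

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "StructureModel",
    "Selection",
    "read_structure",
    "write_structure",
    "apply_transform",
    "select",
    "merge",
]

_PDB_CHAIN_ALPHABET = string.ascii_uppercase + string.ascii_lowercase + string.digits


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray
    b_factor: float = 0.0
    occupancy: float = 1.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.position)):
            raise InvalidArgumentError(f"atom {self.name}: non-finite position")
        if not 0.0 <= self.occupancy <= 1.0:
            raise InvalidArgumentError(f"atom {self.name}: occupancy outside [0, 1]")

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.position.copy(), self.b_factor, self.occupancy)


@dataclass
class Residue:
    seqnum: int
    name: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def copy(self) -> "Residue":
        return Residue(self.seqnum, self.name, [a.copy() for a in self.atoms])


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, seqnum: int) -> Residue | None:
        for r in self.residues:
            if r.seqnum == seqnum:
                return r
        return None

    def copy(self) -> "Chain":
        return Chain(self.chain_id, [r.copy() for r in self.residues])

    def validate(self):
        nums = [r.seqnum for r in self.residues]
        if any(b <= a for a, b in zip(nums, nums[1:])):
            raise InvalidArgumentError(
                f"chain {self.chain_id}: residue numbers not strictly increasing"
            )


class StructureModel:
    """Ordered collection of chains with rigid-transform semantics.

    ``metadata`` carries the title, provenance tags and annotations such as
    the dimer body frame or lattice indices; it travels with in-memory
    copies but only the title survives file round trips.
    """

    def __init__(self, chains: list[Chain] | None = None, metadata: dict | None = None):
        self.chains: list[Chain] = chains or []
        self.metadata: dict = metadata or {}
        seen = set()
        for ch in self.chains:
            if ch.chain_id in seen:
                raise ChainCollisionError(f"duplicate chain id {ch.chain_id!r}")
            seen.add(ch.chain_id)
            ch.validate()

    # -- basic structure access ------------------------------------------------

    def chain(self, chain_id: str) -> Chain | None:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        return None

    def iter_atoms(self):
        for ch in self.chains:
            for res in ch.residues:
                for atom in res.atoms:
                    yield ch, res, atom

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)

    @property
    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)

    def coords(self) -> np.ndarray:
        """All atom positions as an (N, 3) array, in hierarchy order."""
        if self.n_atoms == 0:
            return np.empty((0, 3))
        return np.stack([a.position for _, _, a in self.iter_atoms()])

    def set_coords(self, coords: np.ndarray):
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise InvalidArgumentError("coordinate array shape mismatch")
        for (_, _, atom), pos in zip(self.iter_atoms(), coords):
            atom.position = pos.copy()

    def centroid(self) -> np.ndarray:
        return self.coords().mean(axis=0)

    def copy(self) -> "StructureModel":
        return StructureModel([c.copy() for c in self.chains], dict(self.metadata))

    # -- transforms ------------------------------------------------------------

    def transformed(self, t: RigidTransform) -> "StructureModel":
        out = self.copy()
        out.set_coords(t.apply(out.coords()))
        return out


@dataclass(frozen=True)
class Selection:
    """One chain, a list of inclusive 1-based residue ranges, optional atom filter."""

    chain_id: str
    ranges: tuple[tuple[int, int], ...] = ()
    atom_names: tuple[str, ...] | None = None

    def __post_init__(self):
        for start, end in self.ranges:
            if start > end:
                raise InvalidArgumentError(f"selection range {start}-{end}: start > end")

    @classmethod
    def parse(cls, text: str) -> "Selection":
        """Parse ``chain:start-end[,start-end...][@atomname[,atomname...]]``."""
        body, _, atoms = text.partition("@")
        atom_names = tuple(a.strip() for a in atoms.split(",")) if atoms else None
        chain, sep, range_text = body.partition(":")
        if not sep or not chain.strip():
            raise ParseError(f"selection {text!r}: expected 'chain:start-end'")
        ranges = []
        for chunk in range_text.split(","):
            chunk = chunk.strip()
            if not chunk:
                continue
            lo, sep2, hi = chunk.partition("-")
            try:
                start = int(lo)
                end = int(hi) if sep2 else start
            except ValueError as exc:
                raise ParseError(f"selection {text!r}: bad range {chunk!r}") from exc
            ranges.append((start, end))
        if not ranges:
            raise ParseError(f"selection {text!r}: no residue range given")
        return cls(chain.strip(), tuple(ranges), atom_names)

    def contains(self, seqnum: int) -> bool:
        return any(lo <= seqnum <= hi for lo, hi in self.ranges)

    def width(self) -> int:
        """Total number of residue positions covered by the ranges."""
        return sum(hi - lo + 1 for lo, hi in self.ranges)


# -- selection / transform / merge operations ---------------------------------


def select(model: StructureModel, sel: Selection) -> StructureModel:
    """Extract the atoms matching a selection into a new model.

    An absent chain yields an empty model with a warning rather than an
    error, so pipelines can probe optional components.
    """
    chain = model.chain(sel.chain_id)
    if chain is None:
        warnings.warn(f"selection chain {sel.chain_id!r} absent from model", stacklevel=2)
        return StructureModel([], dict(model.metadata))
    residues = []
    for res in chain.residues:
        if not sel.contains(res.seqnum):
            continue
        atoms = res.atoms
        if sel.atom_names is not None:
            atoms = [a for a in atoms if a.name in sel.atom_names]
        if atoms:
            residues.append(Residue(res.seqnum, res.name, [a.copy() for a in atoms]))
    chains = [Chain(sel.chain_id, residues)] if residues else []
    return StructureModel(chains, dict(model.metadata))


def selection_atoms(model: StructureModel, sel: Selection) -> list[tuple[Residue, Atom]]:
    """Resolve a selection to (residue, atom) pairs; SelectionError if empty."""
    sub = select(model, sel)
    pairs = [(res, atom) for _, res, atom in sub.iter_atoms()]
    if not pairs:
        raise SelectionError(f"selection {sel.chain_id}:{sel.ranges} resolves to no atoms")
    return pairs


def apply_transform(model: StructureModel, t: RigidTransform) -> StructureModel:
    """Map every atom position by ``t``; all other fields are untouched."""
    return model.transformed(t)


def merge(models: list[StructureModel], chain_relabel_policy: str = "strict") -> StructureModel:
    """Combine models into one.

    Policies
    --------
    ``strict``
        Chain-id collisions raise ChainCollisionError.
    ``suffix``
        Colliding ids gain a deterministic ``~k`` suffix (k = 2, 3, ...).
    ``merge``
        Same-id chains are concatenated residue-wise (residue numbers must
        not overlap); used to join hinged-rod segments that continue a chain.
    """
    if not models:
        raise InvalidArgumentError("merge requires at least one model")
    if chain_relabel_policy not in ("strict", "suffix", "merge"):
        raise InvalidArgumentError(f"unknown relabel policy {chain_relabel_policy!r}")
    out = StructureModel([], dict(models[0].metadata))
    for model in models:
        for ch in model.chains:
            existing = out.chain(ch.chain_id)
            if existing is None:
                out.chains.append(ch.copy())
                continue
            if chain_relabel_policy == "strict":
                raise ChainCollisionError(f"chain id {ch.chain_id!r} occurs in multiple models")
            if chain_relabel_policy == "suffix":
                k = 2
                while out.chain(f"{ch.chain_id}~{k}") is not None:
                    k += 1
                renamed = ch.copy()
                renamed.chain_id = f"{ch.chain_id}~{k}"
                out.chains.append(renamed)
            else:  # merge
                combined = existing.residues + [r.copy() for r in ch.residues]
                combined.sort(key=lambda r: r.seqnum)
                existing.residues = combined
                existing.validate()
    return out


# -- file I/O (gemmi-backed) ---------------------------------------------------


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("pdb", "mmcif", "cif"):
            raise InvalidArgumentError(f"unknown structure format {fmt!r}")
        return "mmcif" if fmt == "cif" else fmt
    lower = str(path).lower()
    if lower.endswith((".cif", ".mmcif")):
        return "mmcif"
    if lower.endswith((".pdb", ".ent")):
        return "pdb"
    raise InvalidArgumentError(f"cannot infer format from path {path!r}; pass format=")


def read_structure(path, format: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a StructureModel.

    The first altloc of each atom is kept; insertion codes are rejected.
    Multiple MODEL blocks (as produced for >62-chain assemblies) are
    concatenated with ``suffix`` collision handling.
    """
    fmt = _infer_format(path, format)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if len(st) == 0 or all(len(m) == 0 for m in st):
        raise ParseError(f"{path}: no coordinate records found")
    models = []
    for gm in st:
        chains = []
        for gc in gm:
            residues = []
            for gr in gc:
                if gr.seqid.icode not in (" ", "", "\0"):
                    raise ParseError(
                        f"{path}: insertion code {gr.seqid.icode!r} at "
                        f"{gc.name} {gr.seqid.num} is not supported"
                    )
                atoms = []
                seen_names = set()
                for ga in gr:
                    if ga.name in seen_names:  # keep first altloc only
                        continue
                    seen_names.add(ga.name)
                    atoms.append(
                        Atom(
                            ga.name,
                            ga.element.name if ga.element else "X",
                            np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                            ga.b_iso,
                            min(max(ga.occ, 0.0), 1.0),
                        )
                    )
                residues.append(Residue(gr.seqid.num, gr.name, atoms))
            chains.append(Chain(gc.name, residues))
        models.append(StructureModel(chains, {"title": st.name or ""}))
    if len(models) == 1:
        return models[0]
    return merge(models, chain_relabel_policy="suffix")


def _to_gemmi(model: StructureModel, chain_ids: dict[str, str] | None = None) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = str(model.metadata.get("title", "kinetomt model"))
    gm = gemmi.Model("1")
    for ch in model.chains:
        gc = gemmi.Chain(chain_ids[ch.chain_id] if chain_ids else ch.chain_id)
        for res in ch.residues:
            gr = gemmi.Residue()
            gr.name = res.name
            gr.seqid = gemmi.SeqId(res.seqnum, " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                try:
                    ga.element = gemmi.Element(atom.element)
                except (RuntimeError, ValueError):
                    ga.element = gemmi.Element("X")
                ga.pos = gemmi.Position(*atom.position)
                ga.b_iso = atom.b_factor
                ga.occ = atom.occupancy
                gr.add_atom(ga)
            gc.add_residue(gr)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_structure(model: StructureModel, path, format: str | None = None) -> dict[str, str]:
    """Write PDB or mmCIF; returns the chain-id map actually written.

    mmCIF preserves chain ids verbatim.  PDB relabels multi-character ids
    and assemblies beyond 62 chains deterministically over A-Z, a-z, 0-9,
    splitting across MODEL records when the alphabet is exhausted.
    """
    fmt = _infer_format(path, format)
    if fmt == "mmcif":
        st = _to_gemmi(model)
        st.make_mmcif_document().write_file(str(path))
        return {c.chain_id: c.chain_id for c in model.chains}

    ids = [c.chain_id for c in model.chains]
    needs_relabel = len(ids) > len(_PDB_CHAIN_ALPHABET) or any(len(i) != 1 for i in ids)
    if not needs_relabel:
        st = _to_gemmi(model)
        st.write_pdb(str(path))
        return {i: i for i in ids}

    chain_map = {}
    blocks: list[list[Chain]] = [[]]
    for k, ch in enumerate(model.chains):
        label = _PDB_CHAIN_ALPHABET[k % len(_PDB_CHAIN_ALPHABET)]
        if blocks[-1] and k % len(_PDB_CHAIN_ALPHABET) == 0:
            blocks.append([])
        chain_map[ch.chain_id] = label
        renamed = ch.copy()
        renamed.chain_id = label
        blocks[-1].append(renamed)

    st = gemmi.Structure()
    st.name = str(model.metadata.get("title", "kinetomt model"))
    for bi, block in enumerate(blocks, start=1):
        sub = _to_gemmi(StructureModel(block, model.metadata))
        gm = sub[0].clone()
        gm.num = bi
        st.add_model(gm)
    st.setup_entities()
    doc_lines = [f"REMARK  99 CHAIN MAP {orig} -> {new}" for orig, new in chain_map.items()]
    st.raw_remarks = doc_lines
    st.write_pdb(str(path))
    return chain_map
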