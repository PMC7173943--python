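"""Coordinate data model, PDB reading/writing, and the distance conventions
shared by every structural stage.

Conventions
-----------
* Author (PDB) residue numbering is authoritative; residues are keyed by
  ``(chain_id, seq_number, insertion_code)`` and no renumbering is performed.
* Inter-residue distances are measured between each residue's *interaction
  atom*: the Cβ, or the Cα for glycine (and, with a warning, for any residue
  whose Cβ is missing). Disulfide-bonded cysteine pairs sit at Cβ–Cβ
  distances of roughly 4 Å, which is why this atom pair is the natural
  anchor for crosslink-derived restraints.
* Sulfotyrosine is carried as the ``TYS`` residue code: a tyrosine whose
  phenol oxygen bears a sulfate, treated here purely as a formal charge of
  -1 on the side chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from ._geometry import kabsch
from ._params import STANDARD_RES_TYPES
from .errors import (
    EmptyInputError,
    FormatError,
    IncompleteResidueError,
    ResidueLookupError,
    UnderdeterminedError,
)

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "StructureModel",
    "read_pdb",
    "write_pdb",
    "interaction_atom",
    "pair_distance",
    "superpose",
]

VALID_ROLES = ("receptor", "chemokine", "other")


@dataclass
class AtomRecord:
    name: str
    element: str
    position: np.ndarray  # (3,) Å
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: non-finite coordinates")
        if not 0.0 <= self.occupancy <= 1.0:
            warnings.warn(
                f"atom {self.name}: occupancy {self.occupancy} outside [0, 1], clamping"
            )
            self.occupancy = min(max(self.occupancy, 0.0), 1.0)


@dataclass
class ResidueRecord:
    chain_id: str
    seq_number: int
    res_type: str
    atoms: list[AtomRecord] = field(default_factory=list)
    insertion_code: str = ""

    def __post_init__(self):
        if self.res_type not in STANDARD_RES_TYPES:
            raise ValueError(f"unknown residue type {self.res_type!r}")
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise ValueError(
                f"duplicate atom names in {self.chain_id}{self.seq_number}"
            )

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.seq_number}{self.insertion_code}"


@dataclass
class StructureModel:
    model_id: str
    residues: list[ResidueRecord]
    chain_roles: dict[str, str] = field(default_factory=dict)
    resolution: float | None = None
    provenance: str = ""

    def __post_init__(self):
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (chain, seq_number, insertion_code) keys")
        for chain in {r.chain_id for r in self.residues}:
            self.chain_roles.setdefault(chain, "other")
        for chain, role in self.chain_roles.items():
            if role not in VALID_ROLES:
                raise ValueError(f"chain {chain}: invalid role {role!r}")
        self._index = {r.key: r for r in self.residues}

    def residue(self, res_id) -> ResidueRecord:
        """Resolve a residue id: ``(chain, seq)``, ``(chain, seq, icode)``, or ``"A:12"``."""
        key = _parse_res_id(res_id)
        try:
            return self._index[key]
        except KeyError:
            raise ResidueLookupError(
                f"residue {key} not found in model {self.model_id!r}"
            ) from None

    def has_residue(self, res_id) -> bool:
        return _parse_res_id(res_id) in self._index

    def chain(self, chain_id: str) -> list[ResidueRecord]:
        return [r for r in self.residues if r.chain_id == chain_id]

    def chains_with_role(self, role: str) -> list[str]:
        return sorted(c for c, r in self.chain_roles.items() if r == role)

    def copy(self) -> "StructureModel":
        residues = [
            replace(r, atoms=[replace(a, position=a.position.copy()) for a in r.atoms])
            for r in self.residues
        ]
        return StructureModel(
            self.model_id, residues, dict(self.chain_roles), self.resolution, self.provenance
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a copy with every atom mapped through x -> R x + t."""
        out = self.copy()
        for r in out.residues:
            for a in r.atoms:
                a.position = rotation @ a.position + translation
        return out


def _parse_res_id(res_id) -> tuple[str, int, str]:
    if isinstance(res_id, ResidueRecord):
        return res_id.key
    if isinstance(res_id, tuple):
        if len(res_id) == 2:
            return (str(res_id[0]), int(res_id[1]), "")
        if len(res_id) == 3:
            return (str(res_id[0]), int(res_id[1]), str(res_id[2]))
    if isinstance(res_id, str) and ":" in res_id:
        chain, rest = res_id.split(":", 1)
        digits = "".join(ch for ch in rest if ch.isdigit() or ch == "-")
        icode = rest[len(digits):]
        return (chain, int(digits), icode)
    raise ResidueLookupError(f"cannot interpret residue id {res_id!r}")


def _scan_pdb_lines(path) -> int:
    """Validate coordinate lines, returning the ATOM/HETATM count.

    Raises FormatError naming the first unparseable line.
    """
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                n += 1
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                    int(line[22:26])
                except (ValueError, IndexError):
                    raise FormatError(
                        f"{path}: unparseable coordinate record at line {lineno}: "
                        f"{line.rstrip()!r}"
                    ) from None
    return n


def read_pdb(
    path,
    roles: dict[str, str] | None = None,
    model_index: int = 0,
    model_id: str | None = None,
) -> StructureModel:
    """Read a PDB file into a :class:`StructureModel`.

    Only the model selected by ``model_index`` (default: first) is read.
    HETATM records are ignored except sulfotyrosine (``TYS``). For atoms with
    alternate locations the highest-occupancy conformer is kept, ties broken
    by altloc identifier order.
    """
    if _scan_pdb_lines(path) == 0:
        raise EmptyInputError(f"{path}: no ATOM/HETATM records")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if model_index >= len(st):
        raise EmptyInputError(
            f"{path}: model index {model_index} out of range ({len(st)} models)"
        )
    model = st[model_index]
    residues: list[ResidueRecord] = []
    for chain in model:
        for res in chain:
            if res.name not in STANDARD_RES_TYPES:
                continue  # waters, ligands, and other HETATM entities
            atoms: dict[str, AtomRecord] = {}
            best: dict[str, tuple[float, str]] = {}
            for atom in res:
                rank = (atom.occ, _altloc_rank(atom.altloc))
                if atom.name in atoms and rank <= best[atom.name]:
                    continue
                atoms[atom.name] = AtomRecord(
                    name=atom.name,
                    element=atom.element.name.upper(),
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    occupancy=atom.occ,
                    b_factor=atom.b_iso,
                )
                best[atom.name] = rank
            residues.append(
                ResidueRecord(
                    chain_id=chain.name,
                    seq_number=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                    res_type=res.name,
                    atoms=list(atoms.values()),
                )
            )
    if not residues:
        raise EmptyInputError(f"{path}: no standard amino-acid residues")
    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    return StructureModel(
        model_id=model_id or st.name or str(path),
        residues=residues,
        chain_roles=dict(roles or {}),
        resolution=resolution,
        provenance=f"read from {path}",
    )


def _altloc_rank(altloc: str) -> str:
    # higher rank wins; '' (no altloc) and earlier letters preferred on ties
    return "\xff" if not altloc else chr(255 - ord(altloc))


def write_pdb(model: StructureModel, path) -> None:
    """Write a :class:`StructureModel` as a single-model PDB file."""
    st = gemmi.Structure()
    st.name = model.model_id
    gm = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for res in model.residues:
        if res.chain_id not in chains:
            chains[res.chain_id] = gemmi.Chain(res.chain_id)
        gr = gemmi.Residue()
        gr.name = res.res_type
        gr.seqid = gemmi.SeqId(res.seq_number, res.insertion_code or " ")
        gr.het_flag = "H" if res.res_type == "TYS" else "A"
        for a in res.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*a.position)
            ga.occ = a.occupancy
            ga.b_iso = a.b_factor
            gr.add_atom(ga)
        chains[res.chain_id].add_residue(gr)
    for chain in chains.values():
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


def interaction_atom(residue: ResidueRecord) -> AtomRecord:
    """The restraint-anchoring atom of a residue: Cβ, or Cα for glycine.

    A non-glycine residue missing its Cβ falls back to Cα with a warning;
    a residue with neither atom is an error.
    """
    cb = residue.atom("CB")
    ca = residue.atom("CA")
    if residue.res_type == "GLY":
        if ca is None:
            raise IncompleteResidueError(f"{residue.label}: glycine without CA")
        return ca
    if cb is not None:
        return cb
    if ca is not None:
        warnings.warn(f"{residue.label}: CB missing, falling back to CA")
        return ca
    raise IncompleteResidueError(f"{residue.label}: neither CB nor CA present")


def pair_distance(model: StructureModel, res_a, res_b) -> float:
    """Euclidean Cβ–Cβ (Cα for Gly) distance between two residues, Å."""
    a = interaction_atom(model.residue(res_a))
    b = interaction_atom(model.residue(res_b))
    return float(np.linalg.norm(a.position - b.position))


def superpose(
    mobile: StructureModel,
    reference: StructureModel,
    selection=None,
    atom_names: tuple[str, ...] = ("N", "CA", "C", "O"),
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    ``selection`` is an iterable of residue ids (shared keys by default);
    atoms are matched by (chain, seq_number, insertion_code, atom name).
    Returns ``(rotation, translation, rmsd)`` with the RMSD evaluated over
    the matched selection after the fit.
    """
    if selection is None:
        keys = [r.key for r in mobile.residues if r.key in reference._index]
    else:
        keys = [_parse_res_id(s) for s in selection]
    pm, pr = [], []
    for key in keys:
        try:
            rm = mobile.residue(key)
            rr = reference.residue(key)
        except ResidueLookupError:
            continue
        for name in atom_names:
            am, ar = rm.atom(name), rr.atom(name)
            if am is not None and ar is not None:
                pm.append(am.position)
                pr.append(ar.position)
    if len(pm) < 3:
        raise UnderdeterminedError(
            f"only {len(pm)} matched atoms; need >= 3 for superposition"
        )
    return kabsch(np.array(pm), np.array(pr))
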