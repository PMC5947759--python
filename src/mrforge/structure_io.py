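"""Reading, sanitising and writing protein structures.

The in-memory model is a light hierarchy (:class:`Structure` → :class:`Chain`
→ :class:`Residue` → :class:`Atom`) holding heavy atoms only, with any
additional coordinate sets of a multi-MODEL file stored as plain arrays that
share the topology of the first model.  gemmi does the PDB parsing and
fixed-column writing; everything here is sanitisation and bookkeeping.

Conventions:

* hydrogens are dropped on read — all downstream logic is heavy-atom only;
* author residue numbering is authoritative (score files key on it);
* PDB fixed-column format only, so coordinates round-trip at 3 decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

from ._residues import STANDARD_RESIDUES, WATER_NAMES


class TopologyError(ValueError):
    """Models in a multi-MODEL file do not share one atom topology."""


@dataclass(eq=False)
class Atom:
    """One heavy atom: label, element, Å coordinates, occupancy, B, altloc."""

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")
        if not self.element:
            raise ValueError(f"atom {self.name}: empty element")

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.position.copy(),
                    self.occupancy, self.b_factor, self.altloc)


@dataclass(eq=False)
class Residue:
    name: str
    seq_id: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)
    het: bool = False

    def get(self, atom_name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == atom_name:
                return a
        return None

    @property
    def key(self) -> tuple[int, str]:
        return (self.seq_id, self.icode)

    def copy(self) -> "Residue":
        return Residue(self.name, self.seq_id, self.icode,
                       [a.copy() for a in self.atoms], self.het)


@dataclass(eq=False)
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def copy(self) -> "Chain":
        return Chain(self.chain_id, [r.copy() for r in self.residues])


class Structure:
    """A protein structure: chains of residues plus optional extra models.

    The atom hierarchy carries the coordinates of the first model; further
    coordinate sets (MODEL 2..N of an ensemble file) live in
    ``alt_model_coords`` as ``(n_atoms, 3)`` arrays in flat atom order.
    """

    def __init__(self, chains: Sequence[Chain],
                 alt_model_coords: Sequence[np.ndarray] = ()) -> None:
        self.chains = list(chains)
        if not any(ch.residues for ch in self.chains):
            raise ValueError("structure must contain at least one residue")
        n = self.n_atoms
        self.alt_model_coords: list[np.ndarray] = []
        for arr in alt_model_coords:
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (n, 3):
                raise TopologyError(
                    f"extra model has {arr.shape[0]} atoms, topology has {n}")
            self.alt_model_coords.append(arr)

    # -- iteration ---------------------------------------------------------
    def iter_atoms(self) -> Iterator[Atom]:
        for ch in self.chains:
            for res in ch.residues:
                yield from res.atoms

    def iter_residues(self) -> Iterator[tuple[str, Residue]]:
        for ch in self.chains:
            for res in ch.residues:
                yield ch.chain_id, res

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    @property
    def n_residues(self) -> int:
        return sum(1 for _ in self.iter_residues())

    @property
    def n_models(self) -> int:
        return 1 + len(self.alt_model_coords)

    # -- coordinates -------------------------------------------------------
    def coords(self, model: int = 0) -> np.ndarray:
        """Coordinates of one model as an ``(n_atoms, 3)`` array (copy)."""
        if model == 0:
            return np.array([a.position for a in self.iter_atoms()], dtype=float)
        return self.alt_model_coords[model - 1].copy()

    def set_coords(self, arr: np.ndarray, model: int = 0) -> None:
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (self.n_atoms, 3):
            raise ValueError(f"coordinate array shape {arr.shape} != ({self.n_atoms}, 3)")
        if model == 0:
            for a, xyz in zip(self.iter_atoms(), arr):
                a.position = xyz.copy()
        else:
            self.alt_model_coords[model - 1] = arr.copy()

    def with_coords(self, arr: np.ndarray) -> "Structure":
        """A single-model copy of the topology carrying the given coordinates."""
        s = Structure([ch.copy() for ch in self.chains])
        s.set_coords(arr)
        return s

    def copy(self) -> "Structure":
        return Structure([ch.copy() for ch in self.chains],
                         [m.copy() for m in self.alt_model_coords])

    # -- residue bookkeeping -----------------------------------------------
    def residue_atom_indices(self) -> list[tuple[str, Residue, np.ndarray]]:
        """Per residue: chain id, residue, flat atom indices into coords()."""
        out = []
        i = 0
        for ch in self.chains:
            for res in ch.residues:
                idx = np.arange(i, i + len(res.atoms))
                out.append((ch.chain_id, res, idx))
                i += len(res.atoms)
        return out

    def subset_atoms(self, keep: np.ndarray) -> "Structure":
        """New Structure retaining the flagged flat atom indices.

        Residues left without atoms are dropped; extra models are subset
        consistently.
        """
        keep = np.asarray(keep, dtype=bool)
        chains = []
        i = 0
        for ch in self.chains:
            residues = []
            for res in ch.residues:
                atoms = [a.copy() for a, k in zip(res.atoms, keep[i:i + len(res.atoms)]) if k]
                i += len(res.atoms)
                if atoms:
                    residues.append(Residue(res.name, res.seq_id, res.icode, atoms, res.het))
            if residues:
                chains.append(Chain(ch.chain_id, residues))
        return Structure(chains, [m[keep] for m in self.alt_model_coords])

    def subset_residues(self, kept_ids: Iterable[int]) -> "Structure":
        """New Structure retaining residues whose seq_id is in ``kept_ids``."""
        kept = set(kept_ids)
        mask = np.zeros(self.n_atoms, dtype=bool)
        for _, res, idx in self.residue_atom_indices():
            if res.seq_id in kept:
                mask[idx] = True
        return self.subset_atoms(mask)


# ---------------------------------------------------------------------------
# reading

def _topology_signature(model: gemmi.Model) -> list[tuple]:
    sig = []
    for ch in model:
        for res in ch:
            for atom in res:
                if atom.is_hydrogen():
                    continue
                sig.append((ch.name, res.name, res.seqid.num, res.seqid.icode.strip(),
                            atom.name, atom.altloc))
    return sig


def read_pdb(path: str | Path) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    MODEL/ENDMDL blocks become extra coordinate sets; they must share the
    atom topology of the first model.  Hydrogens are discarded.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise ValueError(f"{path}: no models in file")
    first_sig = _topology_signature(st[0])
    if not first_sig:
        raise ValueError(f"{path}: no ATOM/HETATM records")

    chains: list[Chain] = []
    for gch in st[0]:
        residues = []
        for gres in gch:
            atoms = [Atom(a.name, a.element.name,
                          np.array([a.pos.x, a.pos.y, a.pos.z]),
                          min(max(a.occ, 0.0), 1.0), a.b_iso,
                          a.altloc.strip())
                     for a in gres if not a.is_hydrogen()]
            if atoms:
                residues.append(Residue(gres.name, gres.seqid.num,
                                        gres.seqid.icode.strip(), atoms,
                                        het=(gres.het_flag == "H")))
        if residues:
            chains.append(Chain(gch.name, residues))

    alt = []
    for gmodel in list(st)[1:]:
        if _topology_signature(gmodel) != first_sig:
            raise TopologyError(f"{path}: MODEL blocks differ in atom topology")
        xyz = np.array([[a.pos.x, a.pos.y, a.pos.z]
                        for ch in gmodel for res in ch for a in res
                        if not a.is_hydrogen()])
        alt.append(xyz)
    return Structure(chains, alt)


# ---------------------------------------------------------------------------
# sanitisation

def prepare_input(s: Structure, chain: str) -> Structure:
    """Sanitise a structure for search-model generation.

    Keeps only the selected chain; renames selenomethionine (MSE) to MET
    with SE → SD; for each alternate-location group keeps the
    highest-occupancy conformer (tie → first in file order) and clears its
    altloc tag; drops waters and non-polymer heteroatoms.  Idempotent.
    """
    match = [ch for ch in s.chains if ch.chain_id == chain]
    if not match:
        raise ValueError(f"chain {chain!r} not present "
                         f"(available: {[c.chain_id for c in s.chains]})")
    src = match[0]

    # flat mask over the ORIGINAL structure so extra models stay aligned
    mask = np.zeros(s.n_atoms, dtype=bool)
    kept_meta: list[Residue] = []
    for chain_id, res, idx in s.residue_atom_indices():
        if chain_id != chain:
            continue
        name = res.name
        if name in WATER_NAMES:
            continue
        if name not in STANDARD_RESIDUES and name != "MSE":
            continue
        # altloc pruning: per atom name keep the best conformer
        by_name: dict[str, int] = {}
        for k, a in enumerate(res.atoms):
            prev = by_name.get(a.name)
            if prev is None or a.occupancy > res.atoms[prev].occupancy:
                by_name[a.name] = k  # strict '>' keeps the first on ties
        keep_local = sorted(by_name.values())
        mask[idx[keep_local]] = True
        atoms = []
        for k in keep_local:
            a = res.atoms[k].copy()
            a.altloc = ""
            if name == "MSE" and a.name == "SE":
                a.name, a.element = "SD", "S"
            atoms.append(a)
        out_name = "MET" if name == "MSE" else name
        kept_meta.append(Residue(out_name, res.seq_id, res.icode, atoms, het=False))

    if not kept_meta:
        raise ValueError(f"chain {chain!r} contains no polymer residues")
    seen = set()
    for res in kept_meta:
        if res.key in seen:
            raise ValueError(f"duplicate residue {res.seq_id}{res.icode} in chain {chain}")
        seen.add(res.key)
    return Structure([Chain(chain, kept_meta)], [m[mask] for m in s.alt_model_coords])


# ---------------------------------------------------------------------------
# writing

def _to_gemmi(models: Sequence[tuple[Structure, int]]) -> gemmi.Structure:
    g = gemmi.Structure()
    for num, (s, midx) in enumerate(models, start=1):
        coords = s.coords(midx)
        gm = gemmi.Model(num)
        i = 0
        for ch in s.chains:
            gch = gemmi.Chain(ch.chain_id)
            for res in ch.residues:
                gr = gemmi.Residue()
                gr.name = res.name
                gr.seqid = gemmi.SeqId(res.seq_id, res.icode or " ")
                gr.het_flag = "A"
                for a in res.atoms:
                    ga = gemmi.Atom()
                    ga.name = a.name
                    ga.element = gemmi.Element(a.element)
                    ga.pos = gemmi.Position(*coords[i])
                    ga.occ = a.occupancy
                    ga.b_iso = a.b_factor
                    if a.altloc:
                        ga.altloc = a.altloc
                    i += 1
                    gr.add_atom(ga)
                gch.add_residue(gr)
            gm.add_chain(gch)
        g.add_model(gm)
    return g


def write_models(models: Sequence[Structure], path: str | Path,
                 multi_model: bool = False) -> Path:
    """Write structures to a PDB file.

    With ``multi_model`` every coordinate set of every structure becomes one
    MODEL block numbered 1..N; otherwise exactly one single-model structure
    is expected and written as a plain PDB.
    """
    if len(models) == 0:
        raise ValueError("no models to write")
    flat = [(s, m) for s in models for m in range(s.n_models)]
    if not multi_model and len(flat) > 1:
        raise ValueError("multiple coordinate sets require multi_model=True")
    g = _to_gemmi(flat)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    g.write_pdb(str(path))
    return path
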