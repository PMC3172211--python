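"""Protein-mannose contact annotation from 3D structures.

A residue is labelled interacting when any of its heavy atoms lies within a
distance cutoff (default 4.0 A, inclusive) of any heavy atom of a mannose
ligand.  Ligands are identified by PDB residue name, by default MAN
(alpha-D-mannose) and BMA (beta-D-mannose).  Only model 1 of multi-model
files is considered; for disordered atoms the highest-occupancy conformer is
kept; waters never count as protein or ligand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .alphabet import DUMMY
from .sequence_io import AnnotatedSequence

log = logging.getLogger(__name__)

try:  # one-letter translations for standard + common modified residues
    from Bio.Data.PDBData import protein_letters_3to1_extended as _3TO1
except ImportError:  # older layouts
    from Bio.Data.SCOPData import protein_letters_3to1 as _3TO1

DEFAULT_LIGANDS = frozenset({"MAN", "BMA"})
DEFAULT_CUTOFF = 4.0


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: tuple[float, float, float]

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")


@dataclass
class Residue:
    position: int  # 1-based sequence position within the chain
    name3: str
    one_letter: str
    atoms: list[Atom]


@dataclass
class StructureModel:
    """Minimal coordinate model: protein chains plus ligand residues."""

    chains: list[tuple[str, list[Residue]]]
    ligands: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        for cid, residues in self.chains:
            positions = [r.position for r in residues]
            if any(b <= a for a, b in zip(positions, positions[1:])):
                raise ValueError(f"chain {cid}: residue positions not increasing")
        for _, residues in self.chains:
            for r in residues:
                for a in r.atoms:
                    if not all(np.isfinite(a.coord)):
                        raise ValueError("non-finite atom coordinate")


@dataclass
class LigandSelection:
    """Which HETATM residues count as ligand, and the contact cutoff in A."""

    residue_names: frozenset[str] = DEFAULT_LIGANDS
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        object.__setattr__(
            self, "residue_names", frozenset(n.upper() for n in self.residue_names)
        )


def _one_letter(name3: str) -> str:
    code = _3TO1.get(name3.upper().strip(), DUMMY)
    if len(code) != 1 or code not in "ACDEFGHIKLMNPQRSTVWY":
        code = DUMMY
    if code == DUMMY:
        log.warning("unknown protein residue name %r mapped to X", name3)
    return code


def read_structure(
    path: str | Path, ligand_names: frozenset[str] = DEFAULT_LIGANDS
) -> StructureModel:
    """Read a PDB file into a :class:`StructureModel` (model 1 only)."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(Path(path).stem, str(path))
    model = next(structure.get_models())

    ligand_names = frozenset(n.upper() for n in ligand_names)
    chains: list[tuple[str, list[Residue]]] = []
    ligands: list[Residue] = []
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            hetflag = res.id[0]
            if hetflag == "W":
                continue
            atoms = _dedupe_altloc(res)
            if hetflag == " ":
                residues.append(
                    Residue(
                        position=len(residues) + 1,
                        name3=res.resname,
                        one_letter=_one_letter(res.resname),
                        atoms=atoms,
                    )
                )
            elif res.resname.strip().upper() in ligand_names:
                ligands.append(
                    Residue(
                        position=res.id[1],
                        name3=res.resname.strip().upper(),
                        one_letter=DUMMY,
                        atoms=atoms,
                    )
                )
        if residues:
            chains.append((chain.id, residues))
    if not chains:
        raise ValueError(f"{path}: no protein chain found")
    return StructureModel(chains=chains, ligands=ligands)


def _best_atom(atom) -> Atom:
    return Atom(
        name=atom.get_name(),
        element=(atom.element or "").strip() or atom.get_name()[:1],
        coord=tuple(float(c) for c in atom.coord),
    )


def _dedupe_altloc(res) -> list[Atom]:
    """Highest-occupancy conformer per atom name; ties broken by altloc id."""
    best: dict[str, tuple[float, str, Atom]] = {}
    for a in res.get_unpacked_list():
        occ = a.get_occupancy() if a.get_occupancy() is not None else 1.0
        alt = a.get_altloc() or " "
        key = a.get_name()
        cand = (-occ, alt, _best_atom(a))
        if key not in best or cand[:2] < best[key][:2]:
            best[key] = cand
    return [v[2] for v in best.values()]


def find_interacting_residues(
    structure: StructureModel, ligand: LigandSelection | None = None
) -> list[AnnotatedSequence]:
    """Label every protein residue by proximity to ligand heavy atoms.

    A residue interacts iff the minimum Euclidean distance between any of
    its heavy atoms and any ligand heavy atom is <= the cutoff.  Returns one
    :class:`AnnotatedSequence` per protein chain, in file order.
    """
    if ligand is None:
        ligand = LigandSelection()
    if not structure.chains:
        raise ValueError("structure contains no protein chain")

    lig_coords = np.array(
        [
            a.coord
            for res in structure.ligands
            if res.name3 in ligand.residue_names
            for a in res.atoms
            if a.is_heavy
        ]
    )
    tree = cKDTree(lig_coords) if len(lig_coords) else None

    out: list[AnnotatedSequence] = []
    for chain_id, residues in structure.chains:
        letters = "".join(r.one_letter for r in residues)
        labels: list[bool] = []
        for r in residues:
            coords = np.array([a.coord for a in r.atoms if a.is_heavy])
            if tree is None or len(coords) == 0:
                labels.append(False)
                continue
            dmin, _ = tree.query(coords, k=1)
            labels.append(bool(np.min(dmin) <= ligand.cutoff))
        out.append(AnnotatedSequence(chain_id=chain_id, residues=letters, labels=labels))
    return out


def brute_force_interacting(
    structure: StructureModel, ligand: LigandSelection | None = None
) -> list[AnnotatedSequence]:
    """Reference annotator: plain double loop over every atom pair."""
    if ligand is None:
        ligand = LigandSelection()
    if not structure.chains:
        raise ValueError("structure contains no protein chain")
    lig_atoms = [
        a.coord
        for res in structure.ligands
        if res.name3 in ligand.residue_names
        for a in res.atoms
        if a.is_heavy
    ]
    out = []
    for chain_id, residues in structure.chains:
        labels = []
        for r in residues:
            hit = False
            for a in r.atoms:
                if not a.is_heavy:
                    continue
                for lc in lig_atoms:
                    d = sum((x - y) ** 2 for x, y in zip(a.coord, lc)) ** 0.5
                    if d <= ligand.cutoff:
                        hit = True
                        break
                if hit:
                    break
            labels.append(hit)
        out.append(
            AnnotatedSequence(
                chain_id=chain_id,
                residues="".join(r.one_letter for r in residues),
                labels=labels,
            )
        )
    return out


def make_toy_complex(
    n_residues: int,
    contact_positions: set[int],
    offset: float = 3.5,
    seed: int = 0,
    cutoff: float = DEFAULT_CUTOFF,
) -> StructureModel:
    """Synthetic extended chain plus a pseudo-mannose for testing annotation.

    Residues are single-CA glycines spaced along x; the MAN ligand gets one
    atom exactly ``offset`` A from each requested contact residue and far
    from everything else.  Deterministic under ``seed``.
    """
    if n_residues < 1:
        raise ValueError("need at least one residue")
    if not set(contact_positions) <= set(range(1, n_residues + 1)):
        raise ValueError("contact positions outside 1..n_residues")
    if offset <= 0:
        raise ValueError("offset must be positive")
    if contact_positions and offset >= cutoff:
        raise ValueError(
            f"offset {offset} >= cutoff {cutoff}: requested contacts infeasible"
        )
    rng = np.random.default_rng(seed)
    spacing = max(5.0, cutoff + 1.5)
    residues = []
    ca = {}
    for i in range(1, n_residues + 1):
        jitter = rng.uniform(-0.1, 0.1, size=2)
        pos = (i * spacing, float(jitter[0]), float(jitter[1]))
        ca[i] = pos
        residues.append(
            Residue(
                position=i,
                name3="GLY",
                one_letter="G",
                atoms=[Atom(name="CA", element="C", coord=pos)],
            )
        )
    lig_atoms = [
        Atom(
            name=f"C{k + 1}",
            element="C",
            coord=(ca[p][0], ca[p][1] + offset, ca[p][2]),
        )
        for k, p in enumerate(sorted(contact_positions))
    ]
    if not lig_atoms:  # parked far from the chain
        lig_atoms = [
            Atom(name="C1", element="C", coord=((n_residues + 20) * spacing, 500.0, 0.0))
        ]
    ligand = Residue(position=n_residues + 1, name3="MAN", one_letter=DUMMY, atoms=lig_atoms)
    return StructureModel(chains=[("A", residues)], ligands=[ligand])


def write_pdb(structure: StructureModel, path: str | Path) -> None:
    """Serialize a StructureModel as minimal PDB (fixture plumbing)."""
    serial = 0
    with open(path, "w") as fh:
        for chain_id, residues in structure.chains:
            for r in residues:
                for a in r.atoms:
                    serial += 1
                    fh.write(_pdb_line("ATOM", serial, a, r, chain_id))
        for r in structure.ligands:
            for a in r.atoms:
                serial += 1
                fh.write(_pdb_line("HETATM", serial, a, r, "L"))
        fh.write("END\n")


def _pdb_line(record: str, serial: int, a: Atom, r: Residue, chain_id: str) -> str:
    x, y, z = a.coord
    return (
        f"{record:<6}{serial:>5} {a.name:^4} {r.name3:>3} {chain_id}"
        f"{r.position:>4}    {x:8.3f}{y:8.3f}{z:8.3f}"
        f"{1.0:6.2f}{0.0:6.2f}          {a.element:>2}\n"
    )
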