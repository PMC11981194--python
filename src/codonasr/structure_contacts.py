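"""Inter-chain contact mapping on a receptor–effector complex structure.

Defines the binding interface the way crystallographic contact listings do:
all heavy-atom pairs between two chains whose Euclidean distance falls in a
window (default 2.5–3.6 Å), with the contacting receptor residues then
merged into contiguous interface regions.  Structures are read with gemmi
(PDB and mmCIF); hydrogens and waters are excluded, and only the blank or
'A' alternate location is taken.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .asr_engine import InterfaceRegion

logger = logging.getLogger(__name__)

_WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom with author residue numbering."""

    chain: str
    residue_index: int
    residue_name: str
    atom_name: str
    element: str
    x: float
    y: float
    z: float

    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass(frozen=True)
class ContactPair:
    """A heavy-atom contact between two chains within the distance window."""

    residue_a: int
    residue_name_a: str
    atom_a: str
    residue_b: int
    residue_name_b: str
    atom_b: str
    distance: float


def read_structure(
    path: str | Path, include_waters: bool = False, include_ligands: bool = True
) -> list[AtomRecord]:
    """Read heavy atoms from a PDB or mmCIF file.

    Hydrogens are always dropped; waters are dropped unless requested.
    Alternate locations other than blank or 'A' are skipped (logged once).
    """
    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    atoms: list[AtomRecord] = []
    skipped_altloc = 0
    model = structure[0]
    for chain in model:
        for residue in chain:
            if residue.name in _WATER_NAMES and not include_waters:
                continue
            if not include_ligands and residue.het_flag == "H":
                continue
            for atom in residue:
                if atom.element.is_hydrogen:
                    continue
                if atom.altloc not in ("\x00", "", "A"):
                    skipped_altloc += 1
                    continue
                atoms.append(
                    AtomRecord(
                        chain=chain.name,
                        residue_index=residue.seqid.num,
                        residue_name=residue.name,
                        atom_name=atom.name,
                        element=atom.element.name,
                        x=atom.pos.x,
                        y=atom.pos.y,
                        z=atom.pos.z,
                    )
                )
    if skipped_altloc:
        logger.info("skipped %d alternate-location atoms (kept blank/'A')", skipped_altloc)
    return atoms


def write_pdb(atoms: Sequence[AtomRecord], path: str | Path) -> None:
    """Write atom records as a minimal single-model PDB file."""
    structure = gemmi.Structure()
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for a in atoms:
        if a.chain not in chains:
            chains[a.chain] = gemmi.Chain(a.chain)
        chain = chains[a.chain]
        if len(chain) == 0 or chain[-1].seqid.num != a.residue_index:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_index, " ")
            chain.add_residue(res)
        atom = gemmi.Atom()
        atom.name = a.atom_name
        atom.element = gemmi.Element(a.element)
        atom.pos = gemmi.Position(a.x, a.y, a.z)
        chain[-1].add_atom(atom)
    for chain in chains.values():
        model.add_chain(chain)
    structure.add_model(model)
    structure.setup_entities()
    structure.write_pdb(str(path))


def find_contacts(
    atoms: Sequence[AtomRecord],
    chain_a: str,
    chain_b: str,
    dmin: float = 2.5,
    dmax: float = 3.6,
) -> list[ContactPair]:
    """All heavy-atom pairs between the two chains with dmin <= d <= dmax.

    Output is deterministically ordered by chain-A residue index, then
    distance.  Uses a k-d tree on the chain-B atoms; results are identical
    to the all-pairs brute force.
    """
    if not 0 < dmin < dmax:
        raise ValueError("require 0 < dmin < dmax")
    a_atoms = [a for a in atoms if a.chain == chain_a]
    b_atoms = [a for a in atoms if a.chain == chain_b]
    if not a_atoms:
        raise ValueError(f"chain {chain_a!r} not found in structure")
    if not b_atoms:
        raise ValueError(f"chain {chain_b!r} not found in structure")
    b_xyz = np.array([[a.x, a.y, a.z] for a in b_atoms])
    tree = cKDTree(b_xyz)
    pairs: list[ContactPair] = []
    for a in a_atoms:
        for j in tree.query_ball_point([a.x, a.y, a.z], dmax):
            b = b_atoms[j]
            d = float(np.linalg.norm(a.position() - b.position()))
            if dmin <= d <= dmax:
                pairs.append(
                    ContactPair(
                        residue_a=a.residue_index,
                        residue_name_a=a.residue_name,
                        atom_a=a.atom_name,
                        residue_b=b.residue_index,
                        residue_name_b=b.residue_name,
                        atom_b=b.atom_name,
                        distance=d,
                    )
                )
    pairs.sort(key=lambda p: (p.residue_a, p.distance, p.residue_b, p.atom_a, p.atom_b))
    return pairs


def contact_residues(pairs: Iterable[ContactPair]) -> list[int]:
    """Sorted unique chain-A residue indices participating in contacts."""
    return sorted({p.residue_a for p in pairs})


def cluster_regions(residues: Sequence[int], gap_tol: int = 15) -> list[InterfaceRegion]:
    """Merge contacting residues into contiguous interface regions.

    Consecutive sorted residues are kept in one region while their index
    difference is at most ``gap_tol``; each region is reported as its
    [min, max] span and labelled interface1, interface2, ... in order.
    """
    if gap_tol < 0:
        raise ValueError("gap_tol must be >= 0")
    res = sorted(set(residues))
    if not res:
        return []
    regions: list[InterfaceRegion] = []
    start = prev = res[0]
    for r in res[1:]:
        if r - prev > gap_tol:
            regions.append(InterfaceRegion(f"interface{len(regions) + 1}", start, prev))
            start = r
        prev = r
    regions.append(InterfaceRegion(f"interface{len(regions) + 1}", start, prev))
    return regions
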