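"""Docked-pose ensemble filtering and receptor contact-frequency mapping.

Applies two geometric filters to rigid-body protein-RNA docking poses —
receptor too close to an RNA terminal nucleotide, and RNA overlapping partner
chains of a larger reference complex — then maps, per receptor residue, the
fraction of retained poses in which the residue contacts the RNA.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "AtomRecord",
    "Pose",
    "PoseEnsemble",
    "ContactFrequencyMap",
    "FilterReport",
    "read_structure",
    "write_pdb",
    "min_distance",
    "filter_terminal_proximity",
    "filter_reference_clash",
    "residue_contact_set",
    "contact_frequency",
    "load_ensemble",
    "coords",
]

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}
RNA_RESIDUES = {"A", "U", "G", "C", "RA", "RU", "RG", "RC", "ADE", "URA", "GUA", "CYT"}
WATER = {"HOH", "WAT", "DOD"}
IONS = {"NA", "K", "CL", "MG", "CA", "ZN", "MN", "FE", "CU", "NI", "CO", "SO4", "PO4"}


@dataclass(frozen=True)
class AtomRecord:
    atom_name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    xyz: tuple[float, float, float]
    molecule_class: str  # "protein" | "rna" | "other"

    def __post_init__(self):
        if not all(np.isfinite(self.xyz)):
            raise ValueError(f"non-finite coordinates for atom {self.atom_name}")


def _molecule_class(residue_name: str) -> str:
    r = residue_name.strip().upper()
    if r in AMINO_ACIDS:
        return "protein"
    if r in RNA_RESIDUES:
        return "rna"
    return "other"


def coords(atoms: Sequence[AtomRecord]) -> np.ndarray:
    return np.array([a.xyz for a in atoms], dtype=float)


@dataclass
class Pose:
    """One docked RNA placement (RNA atoms only, receptor frame)."""

    pose_id: str
    rna_atoms: list[AtomRecord]
    source: str = ""

    def __post_init__(self):
        if not self.rna_atoms:
            raise ValueError(f"{self.pose_id}: pose has no RNA atoms")

    def terminal_atoms(self) -> list[AtomRecord]:
        """Atoms of the first and last nucleotide of each RNA chain."""
        by_chain: dict[str, list[int]] = {}
        for a in self.rna_atoms:
            by_chain.setdefault(a.chain_id, []).append(a.residue_index)
        terminals = {
            (c, f(idx)) for c, idx in by_chain.items() for f in (min, max)
        }
        return [
            a for a in self.rna_atoms if (a.chain_id, a.residue_index) in terminals
        ]


@dataclass
class PoseEnsemble:
    receptor: list[AtomRecord]
    poses: list[Pose]
    reference_complex: list[AtomRecord] | None = None


@dataclass
class FilterReport:
    n_input: int
    n_dropped_terminal: int
    n_dropped_clash: int
    n_dropped_both: int
    n_retained: int

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_dropped_terminal": self.n_dropped_terminal,
            "n_dropped_clash": self.n_dropped_clash,
            "n_dropped_both": self.n_dropped_both,
            "n_dropped_any": self.n_input - self.n_retained,
            "n_retained": self.n_retained,
        }


@dataclass
class ContactFrequencyMap:
    """Per receptor residue: number and fraction of retained poses in contact."""

    residues: list[tuple[str, int, str]]  # (chain_id, residue_index, residue_name)
    contact_counts: np.ndarray
    n_retained_poses: int

    @property
    def frequencies(self) -> np.ndarray:
        if self.n_retained_poses == 0:
            return np.zeros(len(self.residues))
        return self.contact_counts / self.n_retained_poses

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chain_id": [r[0] for r in self.residues],
                "residue_index": [r[1] for r in self.residues],
                "residue_name": [r[2] for r in self.residues],
                "contact_count": self.contact_counts,
                "frequency": self.frequencies,
                "n_retained_poses": self.n_retained_poses,
            }
        )


# ---------------------------------------------------------------------------
# structure IO
# ---------------------------------------------------------------------------

def read_structure(
    pdb_file: str | Path, drop_hydrogens: bool = True
) -> list[AtomRecord]:
    """Parse ATOM/HETATM records into AtomRecords.

    Waters and common ions are dropped; disordered atoms resolve to the
    highest-occupancy altloc; hydrogens are excluded by default (all distance
    criteria are heavy-atom).
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("s", str(pdb_file))
    except Exception as exc:  # pragma: no cover - parser detail
        raise ValueError(f"failed to parse {pdb_file}: {exc}") from exc
    atoms: list[AtomRecord] = []
    models = list(structure.get_models())
    if not models:
        raise ValueError(f"no models/ATOM records found in {pdb_file}")
    model = models[0]
    for chain in model:
        for residue in chain:
            resname = residue.get_resname().strip()
            if resname in WATER or resname in IONS:
                continue
            for atom in residue:
                if atom.is_disordered():
                    atom = max(
                        atom.disordered_get_list(), key=lambda a: a.get_occupancy() or 0.0
                    )
                element = (atom.element or "").strip().upper()
                if drop_hydrogens and element in {"H", "D"}:
                    continue
                x, y, z = atom.get_coord()
                atoms.append(
                    AtomRecord(
                        atom_name=atom.get_name(),
                        element=element,
                        residue_index=residue.get_id()[1],
                        residue_name=resname,
                        chain_id=chain.get_id(),
                        xyz=(float(x), float(y), float(z)),
                        molecule_class=_molecule_class(resname),
                    )
                )
    if not atoms:
        raise ValueError(f"no usable atoms in {pdb_file}")
    return atoms


def write_pdb(
    atoms: Sequence[AtomRecord],
    path: str | Path,
    bfactors: Sequence[float] | None = None,
) -> None:
    """Write AtomRecords as fixed-width ATOM records (PDB v3 columns)."""
    lines = []
    for i, a in enumerate(atoms, start=1):
        b = bfactors[i - 1] if bfactors is not None else 0.0
        name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3s}"
        lines.append(
            f"ATOM  {i % 100000:5d} {name:<4.4s} {a.residue_name:>3.3s} "
            f"{a.chain_id:1.1s}{a.residue_index:4d}    "
            f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
            f"{1.00:6.2f}{b:6.2f}          {a.element:>2.2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def min_distance(a: Sequence[AtomRecord], b: Sequence[AtomRecord]) -> float:
    """Exact minimum Euclidean distance between two atom sets (Å), using a
    k-d tree for the pair search."""
    if not a or not b:
        raise ValueError("min_distance requires two non-empty atom sets")
    xa, xb = coords(a), coords(b)
    if len(xa) > len(xb):
        xa, xb = xb, xa
    tree = cKDTree(xb)
    d, _ = tree.query(xa, k=1)
    return float(d.min())


def filter_terminal_proximity(
    pose: Pose, receptor: Sequence[AtomRecord], threshold_A: float = 5.0
) -> bool:
    """True (keep) unless any receptor atom lies within ``threshold_A`` of any
    atom of a terminal nucleotide (strict <). A single-nucleotide RNA is both
    5' and 3' terminal and is handled normally."""
    terminals = pose.terminal_atoms()
    return not (min_distance(receptor, terminals) < threshold_A)


def filter_reference_clash(
    pose: Pose,
    reference_complex: Sequence[AtomRecord] | None,
    receptor_chain_ids: Iterable[str] = (),
    clash_A: float = 2.5,
) -> bool:
    """True (keep) unless any RNA heavy atom lies within ``clash_A`` of a
    reference polypeptide heavy atom outside the receptor itself.

    With no reference complex the filter is a no-op (logged as a warning).
    """
    if reference_complex is None:
        warnings.warn("no reference complex provided; clash filter is a no-op")
        return True
    exclude = set(receptor_chain_ids)
    partner = [
        a
        for a in reference_complex
        if a.molecule_class == "protein" and a.chain_id not in exclude
    ]
    if not partner:
        return True
    return not (min_distance(pose.rna_atoms, partner) < clash_A)


def residue_contact_set(
    pose: Pose, receptor: Sequence[AtomRecord], contact_A: float = 5.0
) -> set[tuple[str, int]]:
    """Receptor residues with any atom strictly closer than ``contact_A`` to
    any RNA atom, keyed by (chain_id, residue_index)."""
    rna = coords(pose.rna_atoms)
    tree = cKDTree(rna)
    d, _ = tree.query(coords(receptor), k=1)
    out: set[tuple[str, int]] = set()
    for atom, dist in zip(receptor, d):
        if dist < contact_A:
            out.add((atom.chain_id, atom.residue_index))
    return out


def _receptor_residues(receptor: Sequence[AtomRecord]) -> list[tuple[str, int, str]]:
    seen: dict[tuple[str, int], str] = {}
    for a in receptor:
        seen.setdefault((a.chain_id, a.residue_index), a.residue_name)
    return [(c, i, seen[(c, i)]) for c, i in sorted(seen)]


def contact_frequency(
    ensemble: PoseEnsemble,
    terminal_A: float = 5.0,
    clash_A: float = 2.5,
    contact_A: float = 5.0,
) -> tuple[ContactFrequencyMap, FilterReport]:
    """Apply both pose filters, then count per-residue RNA contacts over the
    retained poses. The two filters are independent of each other, so the
    retained set does not depend on application order; the report attributes
    drops to each rule (and to both when a pose violates both)."""
    if not ensemble.poses:
        raise ValueError("ensemble contains no poses")
    receptor_chains = {a.chain_id for a in ensemble.receptor}
    retained: list[Pose] = []
    n_term = n_clash = n_both = 0
    for pose in ensemble.poses:
        keep_term = filter_terminal_proximity(pose, ensemble.receptor, terminal_A)
        keep_clash = filter_reference_clash(
            pose, ensemble.reference_complex, receptor_chains, clash_A
        )
        if keep_term and keep_clash:
            retained.append(pose)
        elif not keep_term and not keep_clash:
            n_both += 1
        elif not keep_term:
            n_term += 1
        else:
            n_clash += 1

    residues = _receptor_residues(ensemble.receptor)
    index = {(c, i): k for k, (c, i, _) in enumerate(residues)}
    counts = np.zeros(len(residues), dtype=int)
    for pose in retained:
        for key in residue_contact_set(pose, ensemble.receptor, contact_A):
            counts[index[key]] += 1
    if not retained:
        warnings.warn("all poses dropped by the filters; empty contact map")
    fmap = ContactFrequencyMap(
        residues=residues, contact_counts=counts, n_retained_poses=len(retained)
    )
    report = FilterReport(
        n_input=len(ensemble.poses),
        n_dropped_terminal=n_term,
        n_dropped_clash=n_clash,
        n_dropped_both=n_both,
        n_retained=len(retained),
    )
    return fmap, report


# ---------------------------------------------------------------------------
# ensemble loading
# ---------------------------------------------------------------------------

MAX_RECEPTOR_RMSD_A = 0.1


def load_ensemble(
    receptor_pdb: str | Path,
    pose_dir: str | Path,
    reference_pdb: str | Path | None = None,
) -> PoseEnsemble:
    """Load a receptor, a directory of pose PDBs, and an optional reference
    complex.

    Pose files may contain the receptor chains as well; the RNA atoms are
    extracted and, when protein atoms are present, their coordinates must
    match the receptor to within 0.1 Å RMSD (rigid-receptor guard).
    """
    receptor = [
        a for a in read_structure(receptor_pdb) if a.molecule_class == "protein"
    ]
    rec_xyz = coords(receptor)
    poses = []
    for path in sorted(Path(pose_dir).glob("*.pdb")):
        atoms = read_structure(path)
        rna = [a for a in atoms if a.molecule_class == "rna"]
        prot = [a for a in atoms if a.molecule_class == "protein"]
        if not rna:
            raise ValueError(f"{path}: no RNA atoms found")
        if prot:
            if len(prot) != len(receptor):
                raise ValueError(f"{path}: receptor atom count differs from reference")
            rmsd = float(np.sqrt(np.mean(np.sum((coords(prot) - rec_xyz) ** 2, axis=1))))
            if rmsd > MAX_RECEPTOR_RMSD_A:
                raise ValueError(
                    f"{path}: receptor RMSD {rmsd:.3f} Å exceeds "
                    f"{MAX_RECEPTOR_RMSD_A} Å; poses must share the receptor frame"
                )
        poses.append(Pose(pose_id=path.stem, rna_atoms=rna, source=str(path)))
    reference = read_structure(reference_pdb) if reference_pdb else None
    return PoseEnsemble(receptor=receptor, poses=poses, reference_complex=reference)


def write_outputs(
    out_dir: str | Path,
    ensemble: PoseEnsemble,
    fmap: ContactFrequencyMap,
    report: FilterReport,
    bfactor_pdb: bool = True,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fmap.to_frame().to_csv(out / "contact_frequency.tsv", sep="\t", index=False)
    (out / "filter_report.json").write_text(json.dumps(report.to_dict(), indent=2))
    if bfactor_pdb:
        freq = dict(zip([(c, i) for c, i, _ in fmap.residues], fmap.frequencies))
        b = [100.0 * freq.get((a.chain_id, a.residue_index), 0.0) for a in ensemble.receptor]
        write_pdb(ensemble.receptor, out / "receptor_contact_freq.pdb", bfactors=b)
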