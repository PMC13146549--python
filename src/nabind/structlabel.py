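"""Residue-level binding labels from protein-nucleic-acid complex structures.

A residue is labeled as binding when any of its heavy atoms lies within
``margin`` (default 0.5 Å) plus the sum of the van der Waals radii of the two
atoms from any nucleic-acid atom in the complex (inclusive boundary).  The
module also provides a CD-HIT-style greedy identity clustering used to build
redundancy-filtered datasets (30% identity by convention).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from Bio import Align
from scipy.spatial import cKDTree

from .records import ProteinRecord

log = logging.getLogger(__name__)

DEFAULT_CONTACT_MARGIN = 0.5  # Å added to the vdW radii sum

NUCLEIC_RESIDUES = {"A", "C", "G", "U", "T", "DA", "DC", "DG", "DT", "DU"}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}

_ONE_TO_THREE = {v: k for k, v in list(_THREE_TO_ONE.items())[:20]}


def _load_radii() -> dict[str, float]:
    text = resources.files("nabind.data").joinpath("vdw_radii.tsv").read_text()
    radii = {}
    for line in text.strip().split("\n")[1:]:
        el, r = line.split("\t")
        radii[el] = float(r)
    return radii


VDW_RADII = _load_radii()
DEFAULT_RADIUS = 1.70  # carbon-like fallback for unknown elements


@dataclass
class AtomRecord:
    element: str
    coords: np.ndarray  # (3,) Å
    radius: float
    chain: str
    residue_index: int  # 0-based index within the extracted chain sequence
    residue_name: str
    author_seq_id: int
    is_nucleic: bool

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.radius <= 0 or not np.isfinite(self.coords).all():
            raise ValueError("invalid atom record")


@dataclass
class BindingLabelSet:
    protein_id: str
    chain: str
    sequence: str
    labels: np.ndarray
    margin: float
    author_numbering: list = field(default_factory=list)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.shape != (len(self.sequence),):
            raise ValueError("label/sequence length mismatch")

    def to_record(self, protein_label: int | None = None) -> ProteinRecord:
        return ProteinRecord(
            id=f"{self.protein_id}_{self.chain}",
            sequence=self.sequence,
            residue_labels=self.labels,
            protein_label=protein_label,
        )


def parse_structure(path: str | Path) -> list[AtomRecord]:
    """Read heavy atoms from a PDB/mmCIF file.

    First model only; alternative conformations reduced to the highest
    occupancy one; hydrogens excluded.  Nucleic chains are flagged by
    residue name.  Unknown elements get a carbon-like default radius with
    a warning.
    """
    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse structure file {path}: {exc}") from exc
    structure.setup_entities()
    structure.remove_alternative_conformations()
    structure.remove_hydrogens()
    if len(structure) == 0:
        raise ValueError(f"no models in {path}")
    model = structure[0]
    atoms: list[AtomRecord] = []
    for chain in model:
        res_counter = -1
        last_seqid = None
        for residue in chain:
            resname = residue.name.strip()
            is_nucleic = resname in NUCLEIC_RESIDUES
            if not is_nucleic and resname not in _THREE_TO_ONE:
                continue  # waters, ions, other ligands
            seqid = (residue.seqid.num, residue.seqid.icode)
            if seqid != last_seqid:
                res_counter += 1
                last_seqid = seqid
            for atom in residue:
                el = atom.element.name.upper()
                if el in ("H", "D"):
                    continue
                radius = VDW_RADII.get(el)
                if radius is None:
                    warnings.warn(f"unknown element {el!r}; using default vdW radius")
                    radius = DEFAULT_RADIUS
                atoms.append(
                    AtomRecord(
                        element=el,
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        radius=radius,
                        chain=chain.name,
                        residue_index=res_counter,
                        residue_name=resname,
                        author_seq_id=residue.seqid.num,
                        is_nucleic=is_nucleic,
                    )
                )
    return atoms


def chain_sequence(atoms: Sequence[AtomRecord], chain: str) -> tuple[str, list[int]]:
    """One-letter sequence of a protein chain plus author numbering per residue."""
    seen: dict[int, tuple[str, int]] = {}
    for a in atoms:
        if a.chain == chain and not a.is_nucleic:
            seen.setdefault(a.residue_index, (a.residue_name, a.author_seq_id))
    seq, numbering = [], []
    for idx in sorted(seen):
        name, author = seen[idx]
        seq.append(_THREE_TO_ONE.get(name, "X"))
        numbering.append(author)
    return "".join(seq), numbering


def label_binding_residues(
    protein_atoms: Sequence[AtomRecord],
    nucleic_atoms: Sequence[AtomRecord],
    margin: float = DEFAULT_CONTACT_MARGIN,
    protein_id: str = "protein",
) -> BindingLabelSet:
    """Apply the contact rule over one protein chain's atoms.

    A residue gets label 1 iff any of its atoms is within
    ``margin + r_vdw(atom) + r_vdw(nucleic atom)`` of any nucleic atom
    (boundary inclusive).
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    if not protein_atoms:
        raise ValueError("empty protein atom set")
    chains = {a.chain for a in protein_atoms}
    if len(chains) != 1:
        raise ValueError("label_binding_residues expects atoms from a single protein chain")
    chain = chains.pop()
    seq, numbering = chain_sequence(protein_atoms, chain)
    labels = np.zeros(len(seq), dtype=np.int8)
    index_map = {idx: i for i, idx in enumerate(sorted({a.residue_index for a in protein_atoms}))}

    if not nucleic_atoms:
        warnings.warn("no nucleic atoms supplied; returning all-zero labels")
    else:
        p_xyz = np.array([a.coords for a in protein_atoms])
        n_xyz = np.array([a.coords for a in nucleic_atoms])
        p_rad = np.array([a.radius for a in protein_atoms])
        n_rad = np.array([a.radius for a in nucleic_atoms])
        # prune with a KD-tree at the largest possible cutoff, then test exactly
        max_cut = margin + p_rad.max() + n_rad.max()
        tree = cKDTree(n_xyz)
        for i, neighbors in enumerate(tree.query_ball_point(p_xyz, max_cut + 1e-9)):
            if not neighbors:
                continue
            d = np.linalg.norm(n_xyz[neighbors] - p_xyz[i], axis=1)
            cut = margin + p_rad[i] + n_rad[neighbors]
            if (d <= cut + 1e-12).any():
                labels[index_map[protein_atoms[i].residue_index]] = 1
    return BindingLabelSet(
        protein_id=protein_id,
        chain=chain,
        sequence=seq,
        labels=labels,
        margin=margin,
        author_numbering=numbering,
    )


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment sequence identity: matches / alignment length."""
    if not a or not b:
        raise ValueError("empty sequence")
    alignment = _aligner().align(a, b)[0]
    counts = alignment.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / length if length else 0.0


def greedy_cluster(
    records: Sequence[ProteinRecord], threshold: float = 0.3
) -> tuple[list[ProteinRecord], dict[str, str]]:
    """CD-HIT-style greedy incremental clustering.

    Records are sorted by length (descending); each joins the first existing
    representative with identity >= threshold, else founds a new cluster.
    Returns (representatives, member_id -> representative_id map).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    reps: list[ProteinRecord] = []
    membership: dict[str, str] = {}
    for rec in sorted(records, key=lambda r: (-len(r.sequence), r.id)):
        assigned = None
        for rep in reps:
            if pairwise_identity(rec.sequence, rep.sequence) >= threshold:
                assigned = rep
                break
        if assigned is None:
            reps.append(rec)
            membership[rec.id] = rec.id
        else:
            membership[rec.id] = assigned.id
    return reps, membership


def build_dataset(
    structure_paths: Iterable[str | Path],
    threshold: float = 0.3,
    margin: float = DEFAULT_CONTACT_MARGIN,
    reference: Sequence[ProteinRecord] = (),
) -> list[ProteinRecord]:
    """Label every protein chain of every parseable complex, deduplicate, and
    redundancy-filter against an optional reference set.

    Exact duplicate sequences collapse to one record; remaining records are
    greedily clustered at ``threshold``; any representative with identity
    >= threshold to a reference sequence is dropped (cross-set overlap
    removal).
    """
    labeled: list[ProteinRecord] = []
    seen_sequences: set[str] = set()
    for path in structure_paths:
        try:
            atoms = parse_structure(path)
        except ValueError as exc:
            log.error("skipping %s: %s", path, exc)
            continue
        nucleic = [a for a in atoms if a.is_nucleic]
        stem = Path(path).stem
        for chain in sorted({a.chain for a in atoms if not a.is_nucleic}):
            chain_atoms = [a for a in atoms if a.chain == chain and not a.is_nucleic]
            if not chain_atoms:
                continue
            label_set = label_binding_residues(chain_atoms, nucleic, margin, protein_id=stem)
            if not label_set.sequence:
                continue
            if label_set.sequence in seen_sequences:
                continue
            seen_sequences.add(label_set.sequence)
            labeled.append(label_set.to_record(protein_label=int(label_set.labels.any())))
    reps, _ = greedy_cluster(labeled, threshold) if labeled else ([], {})
    if reference:
        reps = [
            r
            for r in reps
            if all(pairwise_identity(r.sequence, ref.sequence) < threshold for ref in reference)
        ]
    return reps
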