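"""Desk-scale synthetic benchmark generator.

Emulates the core statistical signature of nucleic-acid-binding proteins:
binding interfaces are short sequence patches enriched in basic/aromatic
residues — R/K/W for DNA binding, R/K/H for RNA binding.  Positive proteins
carry one or more planted patches whose positions are drawn from the planted
alphabet with probability ``enrichment`` (background letters otherwise);
negatives are patch-free.  Residue labels mark patch membership, optionally
corrupted by a small flip noise.  ``generate_toy_complex`` writes a minimal
3D complex whose geometric contact labeling reproduces a record's labels
exactly, so the structure-labeling pipeline can be tested end to end.

None of this mimics real folds or nucleic-acid geometry; it exists so every
pipeline stage is exercisable without downloads.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .records import STANDARD_AA, ProteinRecord
from .structlabel import DEFAULT_CONTACT_MARGIN, _ONE_TO_THREE

PLANTED_ALPHABETS = {"dna": "RKW", "rna": "RKH"}


@dataclass
class SyntheticSpec:
    n_proteins: int = 200
    length_range: tuple[int, int] = (60, 120)
    patch_count_range: tuple[int, int] = (1, 3)
    patch_length_range: tuple[int, int] = (8, 14)
    enrichment: float = 0.85
    mode: str = "dna"  # planted alphabet: dna -> RKW, rna -> RKH
    label_noise: float = 0.02
    background: dict | None = None  # letter -> prob; default uniform
    positive_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.mode not in PLANTED_ALPHABETS:
            raise ValueError(f"mode must be one of {sorted(PLANTED_ALPHABETS)}")
        for p in (self.enrichment, self.label_noise, self.positive_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        lo, hi = self.length_range
        plo, phi = self.patch_length_range
        clo, chi = self.patch_count_range
        if lo > hi or plo > phi or clo > chi or plo < 1 or clo < 0:
            raise ValueError("invalid range")
        if chi * phi > lo:
            raise ValueError(
                "infeasible spec: maximum total patch length exceeds minimum protein length"
            )

    @property
    def planted_alphabet(self) -> str:
        return PLANTED_ALPHABETS[self.mode]

    def background_probs(self) -> np.ndarray:
        if self.background is None:
            return np.full(20, 1.0 / 20)
        probs = np.array([self.background.get(aa, 0.0) for aa in STANDARD_AA], dtype=float)
        if not np.isclose(probs.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1 over the standard alphabet")
        return probs

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(json.dumps(d, indent=2) + "\n")


def _place_patches(rng, length: int, sizes: list[int]) -> list[tuple[int, int]]:
    """Sample non-overlapping (start, end) intervals; rejection with fallback."""
    for _ in range(200):
        spans = []
        ok = True
        for size in sizes:
            start = int(rng.integers(0, length - size + 1))
            span = (start, start + size)
            if any(not (span[1] <= s or span[0] >= e) for s, e in spans):
                ok = False
                break
            spans.append(span)
        if ok:
            return sorted(spans)
    # dense fallback: pack left to right
    spans, cursor = [], 0
    for size in sizes:
        spans.append((cursor, cursor + size))
        cursor += size
    return spans


def generate_dataset(spec: SyntheticSpec) -> list[ProteinRecord]:
    """Reproducible synthetic records with planted patches and labels."""
    rng = np.random.default_rng(spec.seed)
    bg = spec.background_probs()
    letters = np.array(list(STANDARD_AA))
    planted = list(spec.planted_alphabet)
    n_pos = int(round(spec.n_proteins * spec.positive_fraction))
    records = []
    for i in range(spec.n_proteins):
        positive = i < n_pos
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        seq = rng.choice(letters, size=length, p=bg)
        labels = np.zeros(length, dtype=np.int8)
        if positive:
            n_patches = int(
                rng.integers(spec.patch_count_range[0], spec.patch_count_range[1] + 1)
            )
            sizes = [
                int(rng.integers(spec.patch_length_range[0], spec.patch_length_range[1] + 1))
                for _ in range(n_patches)
            ]
            for start, end in _place_patches(rng, length, sizes):
                labels[start:end] = 1
                for pos in range(start, end):
                    if rng.random() < spec.enrichment:
                        seq[pos] = planted[int(rng.integers(len(planted)))]
                    # else keep the background letter
        if spec.label_noise > 0:
            flips = rng.random(length) < spec.label_noise
            labels = np.where(flips, 1 - labels, labels).astype(np.int8)
        records.append(
            ProteinRecord(
                id=f"syn{i:04d}",
                sequence="".join(seq),
                residue_labels=labels,
                protein_label=int(positive),
            )
        )
    return records


def generate_toy_complex(
    record: ProteinRecord,
    path: str | Path,
    spacing: float = 6.0,
    seed: int = 0,
    margin: float = DEFAULT_CONTACT_MARGIN,
) -> Path:
    """Write a minimal PDB complex consistent with ``record.residue_labels``.

    One CA pseudo-atom per residue along a jittered line (chain A); one
    phosphorus pseudo-atom per labeled residue placed inside the contact
    cutoff of that residue and outside everyone else's (chain B, DA
    residues).  Round-tripping through ``label_binding_residues`` at the
    same ``margin`` recovers the labels exactly.
    """
    if record.residue_labels is None:
        raise ValueError("record has no residue labels")
    r_ca, r_p = 1.70, 1.80  # carbon and phosphorus vdW radii
    cutoff = margin + r_ca + r_p
    offset = 0.75 * cutoff  # nucleic partner sits this far from its residue
    jitter_amp = 0.25
    # neighbor distance must stay outside the cutoff even under worst-case jitter
    worst_dx = spacing - 2 * jitter_amp
    if worst_dx <= 0 or np.hypot(worst_dx, offset - 2 * jitter_amp) <= cutoff + 0.1:
        raise ValueError(f"spacing {spacing} too small for contact cutoff {cutoff}")

    rng = np.random.default_rng(seed)
    structure = gemmi.Structure()
    structure.name = record.id
    model = gemmi.Model("1")
    prot = gemmi.Chain("A")
    nuc = gemmi.Chain("B")
    nuc_count = 0
    for i, (aa, label) in enumerate(zip(record.sequence, record.residue_labels)):
        jit = rng.uniform(-jitter_amp, jitter_amp, size=3)
        pos = np.array([i * spacing, 0.0, 0.0]) + jit
        res = gemmi.Residue()
        res.name = _ONE_TO_THREE.get(aa, "GLY")
        res.seqid = gemmi.SeqId(i + 1, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*pos)
        res.add_atom(atom)
        prot.add_residue(res)
        if label:
            nuc_count += 1
            npos = pos + np.array([0.0, offset, 0.0])
            nres = gemmi.Residue()
            nres.name = "DA"
            nres.seqid = gemmi.SeqId(nuc_count, " ")
            natom = gemmi.Atom()
            natom.name = "P"
            natom.element = gemmi.Element("P")
            natom.pos = gemmi.Position(*npos)
            nres.add_atom(natom)
            nuc.add_residue(nres)
    if nuc_count == 0:
        # keep a nucleic chain present, far beyond any cutoff
        nres = gemmi.Residue()
        nres.name = "DA"
        nres.seqid = gemmi.SeqId(1, " ")
        natom = gemmi.Atom()
        natom.name = "P"
        natom.element = gemmi.Element("P")
        natom.pos = gemmi.Position(0.0, 100.0 * cutoff, 0.0)
        nres.add_atom(natom)
        nuc.add_residue(nres)
    model.add_chain(prot)
    model.add_chain(nuc)
    structure.add_model(model)
    structure.setup_entities()
    path = Path(path)
    structure.write_pdb(str(path))
    return path
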