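import numpy as np
import pytest

from nabind import structlabel, synthetic
from nabind.records import ProteinRecord
from nabind.structlabel import AtomRecord, label_binding_residues


def _atom(x, y, z, element="C", chain="A", res=0, name="ALA", nucleic=False):
    return AtomRecord(
        element=element,
        coords=np.array([x, y, z], dtype=float),
        radius=structlabel.VDW_RADII.get(element, structlabel.DEFAULT_RADIUS),
        chain=chain,
        residue_index=res,
        residue_name=name,
        author_seq_id=res + 1,
        is_nucleic=nucleic,
    )


TWO_ATOM_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  P    DA B   1       3.000   0.000   0.000  1.00  0.00           P
ATOM      3  H   ALA A   1       1.000   0.000   0.000  1.00  0.00           H
END
"""


class TestParseStructure:
    def test_handcrafted_pdb_roundtrip(self, tmp_path):
        path = tmp_path / "toy.pdb"
        path.write_text(TWO_ATOM_PDB)
        atoms = structlabel.parse_structure(path)
        assert len(atoms) == 2  # hydrogen excluded
        ca = next(a for a in atoms if a.element == "C")
        np.testing.assert_allclose(ca.coords, [0.0, 0.0, 0.0])
        da = next(a for a in atoms if a.residue_name == "DA")
        assert da.is_nucleic and da.element == "P"
        assert not ca.is_nucleic

    def test_unparsable_file_rejected(self, tmp_path):
        bad = tmp_path / "bad.cif"
        bad.write_text("this is not a structure\n")
        with pytest.raises(ValueError):
            structlabel.parse_structure(bad)


class TestContactRule:
    # carbon 1.70 + phosphorus 1.80 + margin 0.5 => cutoff 4.0 A
    @pytest.mark.parametrize(
        "distance,expected",
        [(3.9, 1), (4.05, 0), (4.0, 1)],  # inclusive boundary
    )
    def test_cutoff_arithmetic(self, distance, expected):
        prot = [_atom(0, 0, 0)]
        nuc = [_atom(distance, 0, 0, element="P", chain="B", name="DA", nucleic=True)]
        labels = label_binding_residues(prot, nuc, margin=0.5).labels
        assert labels.tolist() == [expected]

    def test_empty_nucleic_set_warns_all_zero(self):
        with pytest.warns(UserWarning):
            ls = label_binding_residues([_atom(0, 0, 0)], [], margin=0.5)
        assert not ls.labels.any()

    def test_negative_margin_rejected(self):
        with pytest.raises(ValueError):
            label_binding_residues([_atom(0, 0, 0)], [], margin=-0.1)

    def test_monotone_in_margin(self):
        rng = np.random.default_rng(0)
        prot = [_atom(*rng.uniform(0, 20, 3), res=i // 3) for i in range(30)]
        nuc = [
            _atom(*rng.uniform(0, 20, 3), element="P", chain="B", name="DA", nucleic=True)
            for _ in range(10)
        ]
        small = label_binding_residues(prot, nuc, margin=0.2).labels
        big = label_binding_residues(prot, nuc, margin=2.0).labels
        assert (big >= small).all()

    def test_matches_bruteforce_all_pairs(self):
        rng = np.random.default_rng(7)
        elements = ["C", "N", "O", "S"]
        prot = [
            _atom(*rng.uniform(0, 30, 3), element=elements[i % 4], res=i // 4)
            for i in range(200)
        ]
        nuc = [
            _atom(*rng.uniform(0, 30, 3), element=e, chain="B", name="DA", nucleic=True)
            for e in rng.choice(["P", "O", "N", "C"], size=60)
        ]
        margin = 0.5
        got = label_binding_residues(prot, nuc, margin=margin).labels
        n_res = max(a.residue_index for a in prot) + 1
        expected = np.zeros(n_res, dtype=int)
        for a in prot:
            for b in nuc:
                d = np.linalg.norm(a.coords - b.coords)
                if d <= margin + a.radius + b.radius:
                    expected[a.residue_index] = 1
        np.testing.assert_array_equal(got, expected)


class TestIdentityAndClustering:
    def test_identical_sequences_are_fully_identical(self):
        assert structlabel.pairwise_identity("MKRW", "MKRW") == 1.0

    def test_single_mismatch_identity(self):
        assert structlabel.pairwise_identity("AAAA", "AAAT") == 0.75

    def test_disjoint_alphabets_near_zero(self):
        assert structlabel.pairwise_identity("AAAAAA", "RRRRRR") <= 0.05

    def test_all_identical_records_collapse(self):
        recs = [ProteinRecord(f"r{i}", "MKRWLAEH") for i in range(5)]
        reps, members = structlabel.greedy_cluster(recs, 0.3)
        assert len(reps) == 1
        assert len(set(members.values())) == 1

    def test_unrelated_records_stay_separate(self):
        rng = np.random.default_rng(0)
        a = "".join(rng.choice(list("ACDEFGHIKLMN"), 60))
        b = "".join(rng.choice(list("PQRSTVWY"), 60))
        assert structlabel.pairwise_identity(a, b) < 0.3
        reps, _ = structlabel.greedy_cluster(
            [ProteinRecord("a", a), ProteinRecord("b", b)], 0.3
        )
        assert len(reps) == 2

    def test_threshold_one_keeps_distinct_sequences(self):
        recs = [ProteinRecord("a", "MKRW"), ProteinRecord("b", "MKRV")]
        reps, _ = structlabel.greedy_cluster(recs, 1.0)
        assert len(reps) == 2

    def test_every_removed_record_matches_its_representative(self):
        rng = np.random.default_rng(3)
        base = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 50))
        recs = [ProteinRecord("base", base)]
        for i in range(6):
            seq = list(base)
            for pos in rng.choice(50, size=rng.integers(0, 20), replace=False):
                seq[pos] = rng.choice(list("ACDEFGHIKLMNPQRSTVWY"))
            recs.append(ProteinRecord(f"v{i}", "".join(seq)))
        reps, members = structlabel.greedy_cluster(recs, 0.5)
        rep_seqs = {r.id: r.sequence for r in reps}
        for rec in recs:
            rep_id = members[rec.id]
            if rep_id != rec.id:
                assert (
                    structlabel.pairwise_identity(rec.sequence, rep_seqs[rep_id]) >= 0.5
                )

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            structlabel.greedy_cluster([], 0.0)


class TestBuildDataset:
    def _complex_paths(self, tmp_path, n=4, seed=0):
        spec = synthetic.SyntheticSpec(
            n_proteins=n,
            length_range=(20, 30),
            patch_count_range=(1, 2),
            patch_length_range=(4, 8),
            seed=seed,
            label_noise=0.0,
        )
        records = synthetic.generate_dataset(spec)
        paths = []
        for rec in records:
            p = tmp_path / f"{rec.id}.pdb"
            synthetic.generate_toy_complex(rec, p, seed=seed)
            paths.append(p)
        return records, paths

    def test_recovers_planted_labels(self, tmp_path):
        records, paths = self._complex_paths(tmp_path)
        built = structlabel.build_dataset(paths, threshold=0.3)
        by_seq = {r.sequence: r for r in built}
        recovered = 0
        for rec in records:
            match = by_seq.get(rec.sequence)
            if match is not None:
                np.testing.assert_array_equal(match.residue_labels, rec.residue_labels)
                recovered += 1
        assert recovered >= 1  # clustering may merge similar records

    def test_duplicate_structure_collapses(self, tmp_path):
        records, paths = self._complex_paths(tmp_path, n=1)
        built = structlabel.build_dataset([paths[0], paths[0]], threshold=0.3)
        assert len(built) == 1

    def test_reference_overlap_removed(self, tmp_path):
        records, paths = self._complex_paths(tmp_path, n=1)
        ref = [ProteinRecord("ref", records[0].sequence)]
        built = structlabel.build_dataset(paths, threshold=0.3, reference=ref)
        assert built == []
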