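"""Sequence database parsing, curation and background statistics."""

from __future__ import annotations

import numpy as np
import pytest

from protident import (
    ProteinRecord,
    SequenceDatabase,
    abundance_ranking,
    compute_background,
    curate,
    read_fasta,
    write_fasta,
)
from protident.alphabet import AMINO_ACIDS
from protident.database import curation_report


def _write_fasta(path, entries):
    path.write_text("".join(f">{acc}\n{seq}\n" for acc, seq in entries))


class TestReadFasta:
    def test_clean_entries_parse_identically(self, tmp_path):
        p = tmp_path / "db.fasta"
        _write_fasta(p, [("P1", "ACDEFG"), ("P2", "MKLV")])
        db = read_fasta(p)
        assert db.n == 2
        assert [r.accession for r in db.records] == ["P1", "P2"]
        assert db.records[0].sequence == "ACDEFG"

    def test_selenocysteine_maps_to_cysteine(self, tmp_path):
        p = tmp_path / "db.fasta"
        _write_fasta(p, [("P1", "AUG")])
        db = read_fasta(p)
        assert db.records[0].sequence == "ACG"

    def test_pyrrolysine_maps_to_lysine_and_lowercase_uppercased(self, tmp_path):
        p = tmp_path / "db.fasta"
        _write_fasta(p, [("P1", "aOg")])
        assert read_fasta(p).records[0].sequence == "AKG"

    def test_record_with_unknown_residue_dropped_and_counted(self, tmp_path):
        p = tmp_path / "db.fasta"
        _write_fasta(p, [("P1", "ACDX"), ("P2", "MKLV")])
        db = read_fasta(p)
        assert db.n == 1
        assert db.meta["n_dropped"] == 1
        assert db.meta["dropped"] == ["P1"]

    def test_no_valid_records_raises(self, tmp_path):
        p = tmp_path / "db.fasta"
        _write_fasta(p, [("P1", "XXXX")])
        with pytest.raises(ValueError):
            read_fasta(p)

    def test_round_trip_preserves_records(self, tmp_path, small_db):
        p = tmp_path / "out.fasta"
        write_fasta(small_db, p)
        back = read_fasta(p)
        assert [(r.accession, r.sequence) for r in back.records] == [
            (r.accession, r.sequence) for r in small_db.records
        ]

    def test_gzip_round_trip(self, tmp_path, tiny_db):
        p = tmp_path / "out.fasta.gz"
        write_fasta(tiny_db, p)
        back = read_fasta(p)
        assert back.n == tiny_db.n


class TestCurate:
    def test_percentile_cut_linear_interpolation(self):
        # lengths 1..100: the 99th percentile interpolates to 99.01, so only
        # the length-100 record is strictly above it
        records = [ProteinRecord(f"P{i:03d}", "A" * i) for i in range(1, 101)]
        db = SequenceDatabase.from_records(records)
        out = curate(db, percentile=0.99)
        assert out.length_percentile_cut == pytest.approx(99.01)
        assert out.n == 99
        assert max(len(r) for r in out.records) == 99

    def test_percentile_one_removes_nothing(self, small_db):
        assert curate(small_db, percentile=1.0).n == small_db.n

    def test_extreme_outlier_excluded(self):
        # a titin-scale 34 350-residue record among ordinary ones
        records = [ProteinRecord(f"P{i:03d}", "ACDEFGHIKL" * 40) for i in range(99)]
        records.append(ProteinRecord("TITIN", "M" * 34350))
        out = curate(SequenceDatabase.from_records(records), percentile=0.99)
        assert "TITIN" not in {r.accession for r in out.records}

    def test_idempotent(self, small_db):
        once = curate(small_db, 0.9)
        twice = curate(once, 0.9)
        assert [r.accession for r in twice.records] == [r.accession for r in once.records]
        assert twice.n == once.n

    def test_order_preserved(self, small_db):
        out = curate(small_db, 0.9)
        kept = {r.accession for r in out.records}
        expected = [r.accession for r in small_db.records if r.accession in kept]
        assert [r.accession for r in out.records] == expected

    @pytest.mark.parametrize("bad", [0.0, -0.5, 1.5])
    def test_invalid_percentile_rejected(self, small_db, bad):
        with pytest.raises(ValueError):
            curate(small_db, bad)

    def test_report_lists_all_records(self, small_db):
        out = curate(small_db, 0.9)
        rep = curation_report(small_db, out)
        assert len(rep) == small_db.n
        assert rep["kept"].sum() == out.n
        assert (rep.loc[~rep["kept"], "reason"] != "").all()


class TestBackground:
    def test_hand_counted_frequencies(self):
        db = SequenceDatabase.from_records(
            [ProteinRecord("A1", "AAL"), ProteinRecord("A2", "LLS")]
        )
        bg = compute_background(db)
        idx = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
        assert bg[idx["L"]] == pytest.approx(0.5)
        assert bg[idx["A"]] == pytest.approx(1 / 3)
        assert bg[idx["S"]] == pytest.approx(1 / 6)
        assert bg.sum() == pytest.approx(1.0)

    def test_one_of_each_gives_uniform(self):
        db = SequenceDatabase.from_records([ProteinRecord("A1", AMINO_ACIDS)])
        assert np.allclose(compute_background(db), 1 / 20)

    def test_invariant_to_record_order(self, small_db):
        reversed_db = SequenceDatabase.from_records(small_db.records[::-1])
        assert np.array_equal(compute_background(small_db), compute_background(reversed_db))


class TestAbundanceRanking:
    def test_uniform_ties_break_alphabetically(self):
        assert abundance_ranking(np.full(20, 0.05)) == list(AMINO_ACIDS)

    def test_derived_ranking(self):
        db = SequenceDatabase.from_records(
            [ProteinRecord("A1", "AAL"), ProteinRecord("A2", "LLS")]
        )
        ranking = abundance_ranking(compute_background(db))
        assert ranking[:3] == ["L", "A", "S"]
        assert ranking[3:] == sorted(set(AMINO_ACIDS) - {"L", "A", "S"})


class TestInvariants:
    def test_duplicate_accessions_rejected(self):
        with pytest.raises(ValueError):
            SequenceDatabase.from_records(
                [ProteinRecord("X", "AC"), ProteinRecord("X", "DE")]
            )

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            ProteinRecord("X", "")

    def test_noncanonical_residue_rejected(self):
        with pytest.raises(ValueError):
            ProteinRecord("X", "ABC")
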