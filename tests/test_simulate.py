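"""Sequencer simulation: posterior columns, indel errors, fragments, TSV IO."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protident import (
    DeviceConfig,
    ErrorModel,
    FragmentPlan,
    ProteinRecord,
    apply_errors,
    posterior_column,
    read_readout_tsv,
    sample_fragments,
    simulate_readout,
    write_readout_tsv,
)
from protident.alphabet import AA_INDEX, AMINO_ACIDS


class TestPosteriorColumn:
    def test_detected_residue_splits_remainder_equally(self):
        col = posterior_column("Q", DeviceConfig(p_max=0.5))
        assert col[AA_INDEX["Q"]] == pytest.approx(0.5)
        others = np.delete(col, AA_INDEX["Q"])
        assert np.allclose(others, 0.5 / 19)
        assert col.sum() == pytest.approx(1.0)

    def test_undetected_residue_is_uniform(self):
        col = posterior_column("F", DeviceConfig(p_max=0.9, detection_set=frozenset("LSE")))
        assert np.allclose(col, 1 / 20)

    def test_pmax_at_indistinguishable_limit_is_uniform(self):
        col = posterior_column("W", DeviceConfig(p_max=0.05))
        assert np.allclose(col, 1 / 20)

    def test_noncanonical_rejected(self):
        with pytest.raises(ValueError):
            posterior_column("B", DeviceConfig(p_max=0.5))

    @pytest.mark.parametrize("bad", [0.04, 1.01, -0.1])
    def test_pmax_range_enforced(self, bad):
        with pytest.raises(ValueError):
            DeviceConfig(p_max=bad)

    def test_empty_detection_set_rejected(self):
        with pytest.raises(ValueError):
            DeviceConfig(p_max=0.5, detection_set=frozenset())


class TestSimulateReadout:
    def test_error_free_matrix_has_one_column_per_residue(self, device_half):
        ro = simulate_readout("QFEGSAL", device_half)
        assert ro.matrix.shape == (20, 7)
        assert np.allclose(ro.matrix.sum(axis=0), 1.0)
        for i, aa in enumerate("QFEGSAL"):
            assert ro.matrix[AA_INDEX[aa], i] == pytest.approx(0.5)

    def test_zero_rates_keep_length(self, device_half):
        ro = simulate_readout("QFEGSAL", device_half, ErrorModel(0.0, 0.0, seed=1))
        assert ro.length == 7
        assert (ro.n_insertions, ro.n_deletions) == (0, 0)

    def test_perfect_signal_is_one_hot(self):
        seq = "MKWVTFISLLFLFSSAYS"
        ro = simulate_readout(seq, DeviceConfig(p_max=1.0))
        decoded = "".join(AMINO_ACIDS[i] for i in ro.matrix.argmax(axis=0))
        assert decoded == seq
        assert set(np.unique(ro.matrix)) == {0.0, 1.0}

    def test_empty_sequence_rejected(self, device_half):
        with pytest.raises(ValueError):
            simulate_readout("", device_half)

    def test_fixed_seed_is_reproducible(self, device_half):
        em = ErrorModel(0.2, 0.1, seed=42)
        a = simulate_readout("QFEGSAL" * 10, device_half, em)
        b = simulate_readout("QFEGSAL" * 10, device_half, em)
        assert np.array_equal(a.matrix, b.matrix)

    def test_one_deletion_one_insertion_preserves_width(self, device_half):
        # exact counts: rates 1/7 on a 7-mer round to one of each
        ro = simulate_readout("QFEGSAL", device_half, ErrorModel(1 / 7, 1 / 7, seed=5))
        assert ro.matrix.shape == (20, 7)
        assert (ro.n_deletions, ro.n_insertions) == (1, 1)


class TestApplyErrors:
    def _matrix(self, L, device=DeviceConfig(p_max=0.8)):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=L))
        return simulate_readout(seq, device).matrix, device

    def test_ten_percent_insertions_on_100(self):
        m, dev = self._matrix(100)
        out, n_del, n_ins = apply_errors(m, ErrorModel(0.10, 0.0, seed=1), dev)
        assert (n_del, n_ins) == (0, 10)
        assert out.shape[1] == 110

    def test_ten_percent_deletions_on_100(self):
        m, dev = self._matrix(100)
        out, n_del, n_ins = apply_errors(m, ErrorModel(0.0, 0.10, seed=1), dev)
        assert (n_del, n_ins) == (10, 0)
        assert out.shape[1] == 90

    def test_zero_rates_identity(self):
        m, dev = self._matrix(30)
        out, n_del, n_ins = apply_errors(m, ErrorModel(0.0, 0.0, seed=1), dev)
        assert np.array_equal(out, m)
        assert (n_del, n_ins) == (0, 0)

    def test_deleting_everything_rejected(self):
        m, dev = self._matrix(4)
        with pytest.raises(ValueError):
            apply_errors(m, ErrorModel(0.0, 0.99, seed=1), dev)

    def test_inserted_columns_are_device_posteriors(self):
        dev = DeviceConfig(p_max=0.9)
        m, _ = self._matrix(20, dev)
        out, _, n_ins = apply_errors(m, ErrorModel(0.5, 0.0, seed=3), dev)
        assert n_ins == 10
        valid = {tuple(posterior_column(aa, dev)) for aa in AMINO_ACIDS}
        for col in out.T:
            assert tuple(col) in valid  # originals are posteriors too

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        L=st.integers(5, 60),
        ins=st.floats(0, 0.8),
        dele=st.floats(0, 0.8),
        seed=st.integers(0, 2**16),
    )
    def test_length_arithmetic_and_stochasticity(self, L, ins, dele, seed):
        dev = DeviceConfig(p_max=0.7)
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=L))
        m = simulate_readout(seq, dev).matrix
        n_del_expect = int(np.floor(dele * L + 0.5))
        if n_del_expect >= L:
            return
        out, n_del, n_ins = apply_errors(m, ErrorModel(ins, dele, seed=seed), dev)
        assert n_del == n_del_expect
        assert n_ins == int(np.floor(ins * L + 0.5))
        assert out.shape[1] == L - n_del + n_ins
        assert np.allclose(out.sum(axis=0), 1.0, atol=1e-12)
        assert (out >= 0).all()


class TestSampleFragments:
    def test_start_range_for_long_protein(self):
        rec = ProteinRecord("P", "A" * 411)
        plan = FragmentPlan(length=100, n_fragments=200, seed=1)
        frags = sample_fragments(rec, plan)
        starts = [s for s, _ in frags]
        assert all(0 <= s <= 311 for s in starts)
        assert all(e - s == 100 for s, e in frags)

    def test_short_protein_returns_whole_sequence(self):
        rec = ProteinRecord("P", "A" * 80)
        frags = sample_fragments(rec, FragmentPlan(length=100, n_fragments=3, seed=1))
        assert frags == [(0, 80)] * 3

    def test_requested_number_of_fragments(self):
        rec = ProteinRecord("P", "ACDEFGHIKLMNPQRSTVWY" * 10)
        assert len(sample_fragments(rec, FragmentPlan(25, n_fragments=10, seed=2))) == 10

    def test_invalid_plans_rejected(self):
        with pytest.raises(ValueError):
            FragmentPlan(0, 1)
        with pytest.raises(ValueError):
            FragmentPlan(5, 0)


class TestReadoutTsv:
    def test_round_trip(self, tmp_path, device_half):
        ro = simulate_readout(
            "QFEGSAL", device_half, ErrorModel(1 / 7, 1 / 7, seed=9),
            accession="P00001", fragment=(3, 10),
        )
        path = tmp_path / "readout.tsv"
        write_readout_tsv(ro, path)
        back = read_readout_tsv(path)
        assert np.allclose(back.matrix, ro.matrix, atol=1e-9)
        assert back.source_accession == "P00001"
        assert (back.fragment_start, back.fragment_end) == (3, 10)
        assert (back.n_insertions, back.n_deletions) == (ro.n_insertions, ro.n_deletions)

    def test_header_mismatch_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("X\tY\n0.5\t0.5\n")
        with pytest.raises(ValueError):
            read_readout_tsv(p)
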