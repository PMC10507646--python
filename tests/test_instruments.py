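"""Instrument selection, LD clumping and instrument-strength statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from summarymr import (
    NoInstrumentsError,
    build_instrument_set,
    f_statistic,
    ld_clump,
    select_instruments,
    snp_r2,
)
from summarymr.instruments import read_ld_matrix, write_ld_matrix

from conftest import make_record


def ld_frame(ids, entries=None):
    mat = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for (a, b), r2 in (entries or {}).items():
        mat.loc[a, b] = mat.loc[b, a] = r2
    return mat


class TestSelectInstruments:
    def test_threshold_filter(self):
        records = [
            make_record(snp_id="rs1", pval=1e-8),
            make_record(snp_id="rs2", pval=1e-6),
            make_record(snp_id="rs3", pval=1e-3),
        ]
        assert [r.snp_id for r in select_instruments(records, 5e-7)] == ["rs1"]

    def test_strict_inequality_at_boundary(self):
        kept = select_instruments([make_record(pval=4.9e-8)], 5e-8)
        assert len(kept) == 1
        with pytest.raises(NoInstrumentsError):
            select_instruments([make_record(pval=5e-8)], 5e-8)

    def test_no_instruments_error_carries_threshold(self):
        with pytest.raises(NoInstrumentsError) as err:
            select_instruments([make_record(pval=0.5)], 5e-7)
        assert err.value.p_threshold == 5e-7


class TestLDClump:
    def three_records(self):
        return [
            make_record(snp_id="rs1", pval=1e-9, pos=100_000),
            make_record(snp_id="rs2", pval=1e-8, pos=200_000),
            make_record(snp_id="rs3", pval=1e-7, pos=300_000),
        ]

    def test_greedy_removal_of_linked_snp(self):
        # rs1 is the most significant index; rs2 is linked (r2=0.5 >= 0.001)
        # and within the window, so only rs1 and rs3 survive.
        ld = ld_frame(["rs1", "rs2", "rs3"], {("rs1", "rs2"): 0.5})
        kept = ld_clump(self.three_records(), ld, clump_r2=0.001, window_kb=10_000)
        assert [r.snp_id for r in kept] == ["rs1", "rs3"]

    def test_no_ld_keeps_everything(self):
        kept = ld_clump(self.three_records(), ld_frame(["rs1", "rs2", "rs3"]))
        assert len(kept) == 3

    def test_full_ld_keeps_single_lowest_p(self):
        ld = ld_frame(
            ["rs1", "rs2", "rs3"],
            {("rs1", "rs2"): 1.0, ("rs1", "rs3"): 1.0, ("rs2", "rs3"): 1.0},
        )
        kept = ld_clump(self.three_records(), ld)
        assert [r.snp_id for r in kept] == ["rs1"]

    def test_window_limits_removal(self):
        # Same LD but rs2 moved outside the 10,000 kb window: survives.
        records = self.three_records()
        records[1] = make_record(snp_id="rs2", pval=1e-8, pos=100_000 + 10_000_001)
        ld = ld_frame(["rs1", "rs2", "rs3"], {("rs1", "rs2"): 0.9})
        kept = ld_clump(records, ld)
        assert {r.snp_id for r in kept} == {"rs1", "rs2", "rs3"}

    def test_other_chromosome_never_clumped(self):
        records = self.three_records()
        records[1] = make_record(snp_id="rs2", pval=1e-8, pos=200_000, chrom="2")
        ld = ld_frame(["rs1", "rs2", "rs3"], {("rs1", "rs2"): 0.9})
        kept = ld_clump(records, ld)
        assert {r.snp_id for r in kept} == {"rs1", "rs2", "rs3"}

    def test_missing_ld_pairs_treated_as_unlinked(self, caplog):
        ld = ld_frame(["rs1", "rs2"])  # rs3 absent
        with caplog.at_level("WARNING"):
            kept = ld_clump(self.three_records(), ld)
        assert len(kept) == 3
        assert "assuming r^2 = 0" in caplog.text

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.permutations(range(6)))
    def test_result_invariant_to_input_order(self, order):
        records = [
            make_record(snp_id=f"rs{i}", pval=[1e-9, 1e-8, 1e-8, 1e-7, 1e-6, 1e-5][i],
                        pos=100_000 * (i + 1))
            for i in range(6)
        ]
        ids = [r.snp_id for r in records]
        ld = ld_frame(ids, {("rs0", "rs1"): 0.8, ("rs2", "rs3"): 0.6, ("rs4", "rs5"): 0.4})
        baseline = [r.snp_id for r in ld_clump(records, ld)]
        shuffled = [records[i] for i in order]
        assert [r.snp_id for r in ld_clump(shuffled, ld)] == baseline

    def test_greedy_result_is_maximal_independent_set(self):
        rng = np.random.default_rng(11)
        n = 12
        records = [
            make_record(snp_id=f"rs{i}", pval=float(rng.uniform(1e-12, 1e-6)),
                        pos=50_000 * (i + 1))
            for i in range(n)
        ]
        ids = [r.snp_id for r in records]
        mat = rng.uniform(0, 1, (n, n))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 1.0)
        ld = pd.DataFrame(mat, index=ids, columns=ids)
        kept = ld_clump(records, ld, clump_r2=0.4, window_kb=10_000)
        kept_ids = [r.snp_id for r in kept]
        # no retained pair violates the constraint
        for a in kept_ids:
            for b in kept_ids:
                if a < b:
                    assert ld.loc[a, b] < 0.4
        # every removed SNP is linked to some retained index
        for rec in records:
            if rec.snp_id not in kept_ids:
                assert any(ld.loc[rec.snp_id, k] >= 0.4 for k in kept_ids)

    def test_missing_position_rejected(self):
        with pytest.raises(ValueError, match="position"):
            ld_clump([make_record(pos=None)], None)


class TestFStatistic:
    @pytest.mark.parametrize("r2, n, expected", [
        (0.5, 4, 2.0),
        (0.0, 1000, 0.0),
        (0.01, 423796, 4280.75),
    ])
    def test_closed_form(self, r2, n, expected):
        assert f_statistic(r2, n) == pytest.approx(expected, rel=1e-6)

    @pytest.mark.parametrize("r2, n", [(1.0, 100), (-0.1, 100), (0.5, 2)])
    def test_domain_errors(self, r2, n):
        with pytest.raises(ValueError):
            f_statistic(r2, n)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        r2=st.floats(0.001, 0.9),
        n=st.integers(10, 10**6),
        dr=st.floats(0.0001, 0.05),
        dn=st.integers(1, 1000),
    )
    def test_monotone_in_r2_and_n(self, r2, n, dr, dn):
        base = f_statistic(r2, n)
        assert f_statistic(min(r2 + dr, 0.95), n) >= base
        assert f_statistic(r2, n + dn) > base


class TestSnpR2:
    @pytest.mark.parametrize("eaf, beta, expected", [
        (0.5, 0.0, 0.0),
        (0.5, 0.1, 0.005),
        (0.2, 0.25, 0.02),
    ])
    def test_frequency_variance_formula(self, eaf, beta, expected):
        rec = make_record(eaf=eaf, beta=beta)
        assert snp_r2(rec) == pytest.approx(expected, rel=1e-9)

    def test_missing_eaf_instructs_external_r2(self):
        with pytest.raises(ValueError, match="supply R"):
            snp_r2(make_record(eaf=None))

    def test_clipped_below_one(self):
        rec = make_record(eaf=0.5, beta=100.0)
        assert 0.0 <= snp_r2(rec) < 1.0


class TestBuildInstrumentSet:
    def test_full_screen_with_weak_instrument_warning(self, caplog):
        records = [
            make_record(snp_id="rs1", pval=1e-12, eaf=0.3, beta=0.05, n=400_000,
                        pos=100_000),
            make_record(snp_id="rs2", pval=1e-9, eaf=0.5, beta=0.002, n=400_000,
                        pos=50_000_000),  # tiny effect: weak
            make_record(snp_id="rs3", pval=0.5, pos=90_000_000),
        ]
        with caplog.at_level("WARNING"):
            iset = build_instrument_set(records, ld=None, min_f=10.0)
        assert iset.snp_ids == ["rs1", "rs2"]
        assert iset.per_snp_f["rs1"] > 10.0
        assert "rs2" in iset.weak
        assert "weak instruments" in caplog.text

    def test_aggregate_r2_route(self):
        records = [make_record(snp_id="rs1", pval=1e-12, n=423_796, pos=1)]
        iset = build_instrument_set(records, aggregate_r2=0.01)
        assert iset.per_snp_f["rs1"] == pytest.approx(4280.75, rel=1e-6)


def test_ld_matrix_round_trip(tmp_path):
    ld = ld_frame(["rs1", "rs2"], {("rs1", "rs2"): 0.25})
    path = tmp_path / "ld.tsv"
    write_ld_matrix(ld, path)
    back = read_ld_matrix(path)
    assert np.allclose(back.to_numpy(), ld.to_numpy())
    assert list(back.index) == ["rs1", "rs2"]
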