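"""ROR / information-component statistics and the signal scan."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pvsignal as pv
from pvsignal.dispro import ContingencyTable, compute_ic, compute_ror, ic025_exact


class TestContingency:
    def test_hand_count(self, hand_reports, catatonia_query):
        t = pv.build_contingency(hand_reports, "olanzapine", catatonia_query, "all_pediatric")
        assert (t.a, t.b, t.c, t.d) == (2, 1, 1, 2)
        assert t.N == 6

    def test_empty_band_all_zero(self, hand_reports, catatonia_query):
        t = pv.build_contingency(hand_reports, "olanzapine", catatonia_query, "infant")
        assert (t.a, t.b, t.c, t.d) == (0, 0, 0, 0)

    def test_absent_drug_valid_table(self, hand_reports, catatonia_query):
        t = pv.build_contingency(hand_reports, "clozapine", catatonia_query, "all_pediatric")
        assert (t.a, t.b) == (0, 0)
        assert t.c + t.d == 6

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(a=-1, b=0, c=0, d=0)

    def test_margins_match_generator_ground_truth(self, small_dataset):
        """Contingency margins agree with the generator's bookkeeping."""
        rs, truth = small_dataset
        q = pv.PtQuery(name="catatonia", pts=frozenset({"catatonia"}))
        for band in ("infant", "child", "adolescent"):
            m = truth.margins[band]
            for drug in ("olanzapine", "prednisolone", "pneumococcal vaccine"):
                t = pv.build_contingency(rs, drug, q, band)
                assert t.a == m.pair_counts.get((drug, "catatonia"), 0)
                assert t.a + t.b == m.drug_counts.get(drug, 0)
                assert t.a + t.c == m.pt_counts.get("catatonia", 0)
                assert t.N == m.n_reports


class TestRor:
    def test_balanced_table_is_null(self):
        r = compute_ror(ContingencyTable(a=10, b=10, c=10, d=10))
        assert r.ror == pytest.approx(1.0)
        assert r.low < 1.0 < r.high
        # CI symmetric on the log scale
        assert math.log(r.high) + math.log(r.low) == pytest.approx(0.0, abs=1e-12)

    def test_frozen_example(self):
        r = compute_ror(ContingencyTable(a=8, b=92, c=100, d=9800))
        assert r.ror == pytest.approx(8.522, abs=1e-3)
        assert r.low == pytest.approx(4.030, abs=1e-3)
        assert r.high == pytest.approx(18.020, abs=1e-3)
        assert not r.corrected

    def test_zero_cell_triggers_haldane_correction(self):
        r = compute_ror(ContingencyTable(a=5, b=0, c=100, d=9900))
        assert r.corrected
        assert math.isfinite(r.ror) and math.isfinite(r.high)
        assert r.ror > 1

    def test_pt_absent_from_stratum_is_undefined(self):
        with pytest.raises(ValueError, match="a = c = 0"):
            compute_ror(ContingencyTable(a=0, b=10, c=0, d=90))

    def test_statsmodels_oracle_agreement(self):
        """Woolf CI matches statsmodels Table2x2 on random non-zero tables."""
        sm = pytest.importorskip("statsmodels.api")
        from scipy.stats import norm

        z_exact = norm.ppf(0.975)  # statsmodels uses the exact quantile
        rng = np.random.default_rng(7)
        for _ in range(100):
            a, b, c, d = rng.integers(1, 500, size=4)
            t = ContingencyTable(a=int(a), b=int(b), c=int(c), d=int(d))
            ours = compute_ror(t, z=z_exact)
            theirs = sm.stats.Table2x2([[a, b], [c, d]])
            lo, hi = theirs.oddsratio_confint()
            assert ours.ror == pytest.approx(theirs.oddsratio, rel=1e-12)
            assert ours.low == pytest.approx(lo, rel=1e-9)
            assert ours.high == pytest.approx(hi, rel=1e-9)


@settings(derandomize=True, max_examples=200)
@given(st.tuples(*[st.integers(min_value=1, max_value=400)] * 4))
def test_ror_symmetry(cells):
    """Swapping drug/no-drug rows with case/non-case columns inverts the ROR."""
    a, b, c, d = cells
    fwd = compute_ror(ContingencyTable(a=a, b=b, c=c, d=d))
    rev = compute_ror(ContingencyTable(a=c, b=d, c=a, d=b))
    assert rev.ror == pytest.approx(1.0 / fwd.ror, rel=1e-12)
    assert rev.low == pytest.approx(1.0 / fwd.high, rel=1e-9)
    assert rev.high == pytest.approx(1.0 / fwd.low, rel=1e-9)


@settings(derandomize=True, max_examples=200)
@given(
    st.integers(min_value=1, max_value=100),
    st.integers(min_value=2, max_value=100),
    st.integers(min_value=1, max_value=100),
    st.integers(min_value=1, max_value=1000),
)
def test_monotonicity_in_exposure(a, b, c, d):
    """Shifting one report from drug/no-reaction to drug/reaction (fixed
    margins) strictly increases both the ROR and the IC."""
    t0 = ContingencyTable(a=a, b=b, c=c, d=d)
    t1 = ContingencyTable(a=a + 1, b=b - 1, c=c, d=d)
    assert compute_ror(t1).ror > compute_ror(t0).ror
    assert compute_ic(t1)[0] > compute_ic(t0)[0]


class TestInformationComponent:
    def test_zero_when_observed_equals_expected(self):
        ic, _ = compute_ic(ContingencyTable(a=11, b=99, c=89, d=801))
        assert ic == pytest.approx(0.0, abs=1e-12)

    def test_frozen_example(self):
        ic, ic025 = compute_ic(ContingencyTable(a=8, b=92, c=100, d=9800))
        assert ic == pytest.approx(2.428, abs=1e-3)
        assert ic025 == pytest.approx(1.215, abs=1e-3)

    def test_zero_observed_negative_ic(self):
        ic, ic025 = compute_ic(ContingencyTable(a=0, b=50, c=100, d=850))
        assert ic < 0
        assert ic025 < ic - 4  # credibility bound far below

    def test_empty_stratum_rejected(self):
        with pytest.raises(ValueError, match="N = 0"):
            compute_ic(ContingencyTable(a=0, b=0, c=0, d=0))

    def test_closed_form_close_to_gamma_quantile(self):
        """The IC025 approximation tracks the exact credibility quantile."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            a = int(rng.integers(5, 200))
            b, c = (int(x) for x in rng.integers(0, 500, size=2))
            d = int(rng.integers(1, 50000))
            t = ContingencyTable(a=a, b=b, c=c, d=d)
            assert abs(compute_ic(t)[1] - ic025_exact(t)) < 0.15


class TestSignalCriterion:
    @pytest.mark.parametrize(
        "n,ic025,ror_low,expected",
        [
            (6, 2.2, 45.6, True),   # published haloperidol-in-children row
            (4, 3.0, 10.0, False),  # below the 5-case threshold
            (20, -0.1, 1.5, False),  # IC025 not positive
            (20, 0.5, 1.0, False),  # ROR CI touches 1
            (5, 0.01, 1.01, True),  # boundary inclusions
        ],
    )
    def test_dual_criterion(self, n, ic025, ror_low, expected):
        assert pv.evaluate_signal(n, ic025, ror_low) is expected


class TestSignalScan:
    def _set_with_counts(self, n_drug_cases):
        mk = pv.make_report
        reports = [
            mk(f"case{i}", 14, "years", ["drugx"], ["catatonia"])
            for i in range(n_drug_cases)
        ]
        reports += [
            mk(f"other{i}", 14, "years", ["filler"], ["catatonia"]) for i in range(10)
        ]
        reports += [
            mk(f"bg{i}", 14, "years", ["filler"], ["rash"]) for i in range(500)
        ]
        return pv.ReportSet(reports=reports)

    def test_min_case_threshold_boundary(self, catatonia_query):
        at5 = pv.run_signal_scan(self._set_with_counts(5), catatonia_query, "adolescent")
        assert "drugx" in [s.drug_name for s in at5.rows]
        at4 = pv.run_signal_scan(self._set_with_counts(4), catatonia_query, "adolescent")
        assert "drugx" not in [s.drug_name for s in at4.rows]

    def test_rows_sorted_and_consistent_with_build_contingency(
        self, small_dataset, catatonia_query
    ):
        rs, _ = small_dataset
        table = pv.run_signal_scan(rs, catatonia_query, "adolescent")
        keys = [(-s.n_cases, s.drug_name) for s in table.rows]
        assert keys == sorted(keys)
        for s in table.rows[:5]:
            t = pv.build_contingency(rs, s.drug_name, catatonia_query, "adolescent")
            ror = compute_ror(t)
            ic, ic025 = compute_ic(t)
            assert s.n_cases == t.a
            assert s.ror == pytest.approx(ror.ror)
            assert s.ic025 == pytest.approx(ic025)

    def test_verdict_invariant_to_report_order(self, small_dataset, catatonia_query):
        rs, _ = small_dataset
        fwd = pv.run_signal_scan(rs, catatonia_query, "child")
        rev = pv.run_signal_scan(
            pv.ReportSet(reports=list(reversed(rs.reports))), catatonia_query, "child"
        )
        assert [(s.drug_name, s.is_signal) for s in fwd.rows] == [
            (s.drug_name, s.is_signal) for s in rev.rows
        ]

    def test_empty_case_set_gives_empty_table(self, hand_reports):
        q = pv.PtQuery(name="missing", pts=frozenset({"no such pt"}))
        table = pv.run_signal_scan(hand_reports, q, "all_pediatric")
        assert table.rows == []

    def test_matrix_scan_agrees_with_single_scans(self, small_dataset):
        """The vectorized all-pairs scan equals per-query scans row by row."""
        rs, _ = small_dataset
        pts = ["catatonia", "posturing", "echolalia"]
        flat = pv.scan_all_single_pts(rs, pts, ["infant", "child", "adolescent"])
        for band in ("infant", "child", "adolescent"):
            for pt in pts:
                expect = pv.run_signal_scan(
                    rs, pv.PtQuery(name=pt, pts=frozenset({pt})), band
                )
                got = sorted(
                    (s for b, p, s in flat if b == band and p == pt),
                    key=lambda s: (-s.n_cases, s.drug_name),
                )
                assert [
                    (s.drug_name, s.n_cases, s.ror, s.ic025, s.is_signal) for s in got
                ] == [
                    (s.drug_name, s.n_cases, s.ror, s.ic025, s.is_signal)
                    for s in expect.rows
                ]

    def test_global_background_enlarges_comparator(self, small_dataset, catatonia_query):
        rs, _ = small_dataset
        strat = pv.run_signal_scan(rs, catatonia_query, "adolescent", background="stratum")
        glob = pv.run_signal_scan(rs, catatonia_query, "adolescent", background="global")
        assert {s.drug_name for s in strat.rows} == {s.drug_name for s in glob.rows}
        n_strat = {s.drug_name: s.n_cases for s in strat.rows}
        n_glob = {s.drug_name: s.n_cases for s in glob.rows}
        assert n_strat == n_glob  # cases are band-restricted either way
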