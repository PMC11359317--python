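import numpy as np
import pandas as pd
import pytest

from pvsignal.dispro import (
    ContingencyTable,
    DegenerateMarginError,
    DisproportionalityModel,
    SignalCriteria,
    ZeroCellError,
    build_contingency,
    chi_square,
    evaluate_signal,
    prr,
    ror,
    screen_all,
)

from oracles import chi2_oracle, prr_oracle, ror_oracle


def random_positive_tables(n, seed, low=1, high=2000):
    rng = np.random.default_rng(seed)
    return rng.integers(low, high, size=(n, 4))


class TestROR:
    def test_symmetric_table_has_unit_ror(self):
        est, lo, hi = ror(ContingencyTable(10, 10, 10, 10))
        assert est == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_textbook_table_matches_closed_form(self):
        est, lo, hi = ror(ContingencyTable(10, 90, 100, 9900))
        o_est, o_lo, o_hi = ror_oracle(10, 90, 100, 9900)
        assert est == pytest.approx(11.0)
        assert (lo, hi) == pytest.approx((o_lo, o_hi), rel=1e-9)
        # sanity against the printed rounding of the same quantities
        assert (round(lo, 2), round(hi, 1)) == (5.56, 21.8)

    def test_zero_cell_raises_naming_the_cell(self):
        with pytest.raises(ZeroCellError, match="cell b"):
            ror(ContingencyTable(3, 0, 10, 990))

    def test_haldane_correction_equals_oracle_on_shifted_cells(self):
        est, lo, hi = ror(ContingencyTable(3, 0, 10, 990), correction="haldane_half")
        o = ror_oracle(3.5, 0.5, 10.5, 990.5)
        assert (est, lo, hi) == pytest.approx(o, rel=1e-9)

    def test_unknown_correction_rejected(self):
        with pytest.raises(ValueError):
            ror(ContingencyTable(1, 1, 1, 1), correction="rule-of-three")


class TestPRR:
    def test_equal_proportions_give_unit_prr(self):
        assert prr(ContingencyTable(10, 90, 100, 900)) == pytest.approx(1.0)

    def test_textbook_table(self):
        assert prr(ContingencyTable(10, 90, 100, 9900)) == pytest.approx(10.0)

    def test_zero_b_cell_is_fine(self):
        assert prr(ContingencyTable(3, 0, 10, 990)) == pytest.approx(100.0)

    def test_zero_c_cell_is_undefined(self):
        with pytest.raises(ZeroCellError):
            prr(ContingencyTable(3, 10, 0, 990))


class TestChiSquare:
    def test_independence_gives_zero(self):
        assert chi_square(ContingencyTable(10, 90, 100, 900)) == pytest.approx(0.0)

    def test_textbook_table_with_and_without_yates(self):
        t = ContingencyTable(10, 90, 100, 9900)
        assert chi_square(t) == pytest.approx(chi2_oracle(10, 90, 100, 9900), rel=1e-9)
        assert chi_square(t) == pytest.approx(74.45, abs=0.01)
        assert chi_square(t, yates=True) == pytest.approx(
            chi2_oracle(10, 90, 100, 9900, yates=True), rel=1e-9)
        assert chi_square(t, yates=True) == pytest.approx(66.3, abs=0.05)

    def test_zero_margin_is_degenerate(self):
        with pytest.raises(DegenerateMarginError):
            chi_square(ContingencyTable(0, 0, 5, 5))

    def test_yates_never_exceeds_uncorrected(self):
        for a, b, c, d in random_positive_tables(300, seed=5):
            t = ContingencyTable(int(a), int(b), int(c), int(d))
            assert chi_square(t, yates=True) <= chi_square(t) + 1e-12


def test_oracle_equivalence_on_random_tables():
    """ROR/PRR/chi2 agree with the brute-force formulas to 1e-9 relative."""
    for a, b, c, d in random_positive_tables(1000, seed=11):
        t = ContingencyTable(int(a), int(b), int(c), int(d))
        assert ror(t) == pytest.approx(ror_oracle(a, b, c, d), rel=1e-9)
        assert prr(t) == pytest.approx(prr_oracle(a, b, c, d), rel=1e-9)
        assert chi_square(t) == pytest.approx(chi2_oracle(a, b, c, d), rel=1e-9)


def test_sign_equivalence_ror_prr_crossproduct():
    """ror>1 iff prr>1 iff ad>bc on positive tables."""
    for a, b, c, d in random_positive_tables(1000, seed=13):
        t = ContingencyTable(int(a), int(b), int(c), int(d))
        r, p_, x = ror(t)[0], prr(t), a * d - b * c
        if x != 0:
            assert (r > 1) == (p_ > 1) == (x > 0)


class TestEvaluateSignal:
    def test_two_reports_never_signal(self):
        assert not evaluate_signal(2, 5.0, 10.0, 50.0)

    def test_just_over_every_threshold_signals(self):
        assert evaluate_signal(3, 1.01, 2.1, 4.1)

    def test_ci_low_exactly_one_fails_strict_inequality(self):
        assert not evaluate_signal(3, 1.0, 10.0, 50.0)

    def test_nan_statistics_never_signal(self):
        assert not evaluate_signal(3, float("nan"), 10.0, 50.0)

    def test_thresholds_must_be_positive(self):
        with pytest.raises(ValueError):
            SignalCriteria(min_n=0)

    def test_monotone_in_every_argument(self):
        rng = np.random.default_rng(17)
        for _ in range(2000):
            base = (rng.integers(0, 8), rng.uniform(0, 3), rng.uniform(0, 5),
                    rng.uniform(0, 10))
            bumped = tuple(
                v + rng.exponential(1.0) * (rng.random() < 0.5) for v in base
            )
            if evaluate_signal(*base):
                assert evaluate_signal(*bumped)


class TestBuildContingency:
    def test_hand_enumerated_six_case_universe(self):
        # 2 product+event, 1 product only, 1 event only, 2 neither
        u = pd.DataFrame(
            [("1", "E"), ("2", "E"), ("3", "X"), ("4", "E"), ("5", "X"), ("6", "X")],
            columns=["CASEID", "event"],
        )
        t = build_contingency(u, {"1", "2", "3"}, "E")
        assert t.cells() == (2, 1, 1, 2)
        assert t.n == 6

    def test_unreported_event_has_empty_event_column(self):
        u = pd.DataFrame([("1", "X"), ("2", "X")], columns=["CASEID", "event"])
        t = build_contingency(u, {"1"}, "E")
        assert (t.a, t.c) == (0, 0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            build_contingency(pd.DataFrame(columns=["CASEID", "event"]), {"1"}, "E")

    def test_product_without_cases_is_degenerate(self):
        u = pd.DataFrame([("1", "E")], columns=["CASEID", "event"])
        with pytest.raises(DegenerateMarginError):
            build_contingency(u, {"99"}, "E")

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 1, 1, 1)


class TestScreen:
    def _universe(self, rng, n=400):
        rows = []
        for i in range(n):
            rows.append((str(i), rng.choice(["E1", "E2", "E3", "E4"])))
        return pd.DataFrame(rows, columns=["CASEID", "event"])

    def test_planted_pair_ranks_first_by_ror(self):
        rng = np.random.default_rng(3)
        u = self._universe(rng)
        # product holds half the E1 cases plus a couple of others
        e1 = [str(i) for i in range(400) if u.loc[i, "event"] == "E1"]
        others = [str(i) for i in range(400) if u.loc[i, "event"] != "E1"]
        product = set(e1[::2]) | set(others[:3])
        frame = screen_all(u, {"P": product})
        first = frame.iloc[0]
        assert first["event"] == "E1"
        assert frame.groupby("product")["ror"].apply(
            lambda s: s.dropna().is_monotonic_decreasing).all()

    def test_single_event_universe_one_row_per_product(self):
        u = pd.DataFrame([("1", "E"), ("2", "E"), ("3", "E")], columns=["CASEID", "event"])
        frame = screen_all(u, {"P": {"1"}, "Q": {"2", "3"}})
        assert len(frame) == 2
        assert set(frame["product"]) == {"P", "Q"}

    def test_zero_cell_rows_kept_with_status(self):
        # every product case reports E -> b cell is 0
        u = pd.DataFrame([("1", "E"), ("2", "E"), ("3", "E"), ("4", "X")],
                         columns=["CASEID", "event"])
        frame = screen_all(u, {"P": {"1", "2"}})
        assert (frame["status"] == "zero-cell").any()
        assert not frame.loc[frame["status"] == "zero-cell", "is_signal"].any()

    def test_within_class_comparator_restricts_background(self):
        u = pd.DataFrame(
            [("1", "E"), ("2", "E"), ("3", "X"), ("4", "X"), ("5", "E"), ("6", "X")],
            columns=["CASEID", "event"],
        )
        full = DisproportionalityModel(u, {"P": {"1", "2"}, "Q": {"3", "4"}})
        within = DisproportionalityModel(
            u, {"P": {"1", "2"}, "Q": {"3", "4"}}, comparator="within-class")
        assert full.universe["CASEID"].nunique() == 6
        assert within.universe["CASEID"].nunique() == 4

    def test_results_summary_mentions_criteria(self):
        u = pd.DataFrame([("1", "E"), ("2", "X")], columns=["CASEID", "event"])
        res = DisproportionalityModel(u, {"P": {"1"}}).fit()
        text = res.summary()
        assert "PRR>2.0" in text and "chi2>4.0" in text

    def test_display_frame_rounds_to_two_decimals(self):
        u = pd.DataFrame(
            [("1", "E"), ("2", "E"), ("3", "X"), ("4", "X"), ("5", "X"), ("6", "E")],
            columns=["CASEID", "event"],
        )
        res = DisproportionalityModel(u, {"P": {"1", "3"}}).fit()
        disp = res.display_frame()
        assert (disp["ror"].dropna() == disp["ror"].dropna().round(2)).all()


def test_ci_coverage_under_known_odds_ratio():
    """The 95% log-normal CI covers a known OR at its nominal rate."""
    rng = np.random.default_rng(23)
    p = np.array([0.02, 0.08, 0.10, 0.80])  # OR = (0.02*0.80)/(0.08*0.10) = 2
    true_or = (p[0] * p[3]) / (p[1] * p[2])
    tables = rng.multinomial(50_000, p, size=500)
    hits = 0
    for a, b, c, d in tables:
        _, lo, hi = ror(ContingencyTable(int(a), int(b), int(c), int(d)))
        hits += lo <= true_or <= hi
    assert 0.93 <= hits / len(tables) <= 0.97
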