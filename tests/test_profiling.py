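import numpy as np
import pandas as pd
import pytest

from pvsignal.dates import MISSING_DATE, parse_faers_date
from pvsignal.faers_io import dedup_bundle, filter_primary_suspect
from pvsignal.profiling import (
    compute_onsets,
    crs_overlap,
    demographics_table,
    onset_binning,
    soc_signal_distribution,
    time_to_onset,
)

D = parse_faers_date


class TestTimeToOnset:
    def test_two_week_interval(self):
        assert time_to_onset(D("20230101"), D("20230115")).days == 14

    def test_same_day_is_zero(self):
        assert time_to_onset(D("20230210"), D("20230210")).days == 0

    def test_event_before_start_excluded_as_negative(self):
        onset = time_to_onset(D("20230201"), D("20230115"))
        assert not onset.retained and onset.reason == "negative"

    def test_missing_date_excluded(self):
        onset = time_to_onset(MISSING_DATE, D("20230115"))
        assert onset.reason == "missing"

    def test_partial_precision_excluded_by_default(self):
        onset = time_to_onset(D("202301"), D("20230115"))
        assert onset.reason == "partial"

    def test_mid_period_imputation_recovers_partial(self):
        onset = time_to_onset(D("202301"), D("20230131"), impute_mid=True)
        assert onset.days == 16  # from the imputed Jan 15th

    def test_month_boundary_arithmetic(self):
        assert time_to_onset(D("20230125"), D("20230302")).days == 36


class TestOnsetBinning:
    def test_day_seven_lands_in_first_window(self):
        out = onset_binning([0, 7])
        assert out.loc[out["bin"] == "0-7", "count"].item() == 2

    def test_day_sixty_one_is_late_onset(self):
        out = onset_binning([61])
        assert out.loc[out["bin"] == ">60", "count"].item() == 1

    def test_empty_input_is_all_zero(self):
        out = onset_binning([])
        assert out["count"].sum() == 0
        assert (out["fraction"] == 0).all()

    def test_every_value_lands_in_exactly_one_bin(self):
        values = list(range(0, 120, 3))
        out = onset_binning(values)
        assert out["count"].sum() == len(values)
        assert out["fraction"].sum() == pytest.approx(1.0)

    def test_non_increasing_edges_rejected(self):
        with pytest.raises(ValueError):
            onset_binning([1, 2], edges=(7, 7, 60))

    def test_negative_days_rejected(self):
        with pytest.raises(ValueError):
            onset_binning([-1])


class TestCrsOverlap:
    def _universe(self, pairs):
        return pd.DataFrame(pairs, columns=["CASEID", "event"])

    def test_hand_counted_half_overlap(self):
        # 8 cases with the event, 4 of them also report CRS
        pairs = [(str(i), "Hypoxia") for i in range(8)]
        pairs += [(str(i), "Cytokine release syndrome") for i in range(4)]
        s = crs_overlap(self._universe(pairs), "Hypoxia")
        assert (s.n_event, s.n_with_crs) == (8, 4)
        assert s.rate == 0.5

    def test_no_crs_anywhere_is_zero(self):
        s = crs_overlap(self._universe([("1", "Hypoxia")]), "Hypoxia")
        assert s.rate == 0.0

    def test_full_overlap_is_one(self):
        pairs = [("1", "Hypoxia"), ("1", "Cytokine release syndrome")]
        assert crs_overlap(self._universe(pairs), "Hypoxia").rate == 1.0

    def test_unreported_event_has_undefined_rate(self):
        s = crs_overlap(self._universe([("1", "X")]), "Hypoxia")
        assert s.rate is None

    def test_rate_invariant_under_relabeling_other_events(self):
        pairs = [("1", "Hypoxia"), ("1", "Cytokine release syndrome"),
                 ("2", "Hypoxia"), ("2", "Pyrexia"), ("3", "Headache")]
        u1 = self._universe(pairs)
        u2 = u1.copy()
        u2.loc[u2["event"] == "Pyrexia", "event"] = "Fatigue"
        assert crs_overlap(u1, "Hypoxia").rate == crs_overlap(u2, "Hypoxia").rate


class TestSocDistribution:
    def _signals(self, rows):
        return pd.DataFrame(rows, columns=["product", "event", "soc", "is_signal"])

    def test_single_soc_share_is_one(self):
        frame = self._signals([("P", "E1", "SOC A", True), ("P", "E2", "SOC A", True),
                               ("P", "E3", "SOC A", True)])
        out = soc_signal_distribution(frame)
        assert out["share"].tolist() == [1.0]

    def test_even_split_across_two_socs(self):
        frame = self._signals([
            ("P", "E1", "Nervous system disorders", True),
            ("P", "E2", "Nervous system disorders", True),
            ("P", "E3", "Immune system disorders", True),
            ("P", "E4", "Immune system disorders", True),
        ])
        out = soc_signal_distribution(frame)
        assert sorted(out["share"]) == [0.5, 0.5]

    def test_product_without_signals_is_omitted(self):
        frame = self._signals([("P", "E1", "SOC A", False)])
        assert soc_signal_distribution(frame).empty

    def test_unmapped_event_label_is_configuration_error(self):
        frame = pd.DataFrame([("P", "E1", True)],
                             columns=["product", "event", "is_signal"])
        with pytest.raises(ValueError, match="E1"):
            soc_signal_distribution(frame, soc_map={})


class TestComputeOnsets:
    def test_messy_dates_fires_each_exclusion_once(self, messy_bundle):
        clean = dedup_bundle(messy_bundle)
        cases = filter_primary_suspect(clean.drug, {"tisa": ["TISAGENLECLEUCEL"]})
        onsets, tally = compute_onsets(clean, cases)
        assert tally == {"total": 4, "retained": 1, "missing": 1,
                         "partial": 1, "negative": 1}
        assert onsets["days"].tolist() == [14]

    def test_accounting_telescopes(self, messy_bundle):
        clean = dedup_bundle(messy_bundle)
        cases = filter_primary_suspect(clean.drug, {"tisa": ["TISAGENLECLEUCEL"]})
        _, tally = compute_onsets(clean, cases)
        assert tally["total"] == (tally["retained"] + tally["missing"]
                                  + tally["partial"] + tally["negative"])

    def test_tiny_fixture_onsets(self, tiny_bundle):
        clean = dedup_bundle(tiny_bundle)
        cases = filter_primary_suspect(clean.drug, {"tisa": ["TISAGENLECLEUCEL"]})
        onsets, tally = compute_onsets(clean, cases)
        assert dict(zip(onsets["CASEID"], onsets["days"])) == {"100": 14, "101": 0}
        assert tally["partial"] == 1 and tally["negative"] == 1


class TestDemographics:
    def test_age_binning_follows_cohort_windows(self, tiny_bundle):
        clean = dedup_bundle(tiny_bundle)
        cases = filter_primary_suspect(clean.drug, {"tisa": ["TISAGENLECLEUCEL"]})
        table = demographics_table(clean, cases)
        age = table[table["block"] == "age"].set_index("category")["count"]
        # product cases 100-103 have ages 10, 30, 70, 45
        assert age["<18"] == 1 and age["18-64"] == 2 and age[">=65"] == 1

    def test_blocks_sum_to_case_total_and_pcts_recompute(self, tiny_bundle):
        clean = dedup_bundle(tiny_bundle)
        cases = filter_primary_suspect(clean.drug, {"tisa": ["TISAGENLECLEUCEL"]})
        table = demographics_table(clean, cases)
        total = len(cases["tisa"])
        for block, sub in table.groupby("block"):
            if block == "outcome":   # multi-select, not a partition
                continue
            assert sub["count"].sum() == total, block
            np.testing.assert_allclose(sub["pct"], 100.0 * sub["count"] / total)

    def test_all_missing_fields_fall_into_not_specified(self):
        from pvsignal.faers_io import CaseBundle
        demo = pd.DataFrame([{"PRIMARYID": "1", "CASEID": "1", "FDA_DT": "20230101",
                              "EVENT_DT": "", "AGE": "", "AGE_COD": "", "SEX": "",
                              "OCCP_COD": "", "OCCR_COUNTRY": ""}]).astype(str)
        empty = pd.DataFrame(columns=["PRIMARYID", "CASEID", "OUTC_COD", "INDI_PT",
                                      "ROLE_COD", "DRUGNAME", "START_DT"])
        bundle = CaseBundle(demo=demo, drug=empty, reac=empty, ther=empty,
                            outc=empty, indi=empty)
        table = demographics_table(bundle, {"p": {"1"}})
        for block in ("sex", "age", "reporter"):
            sub = table[table["block"] == block]
            assert sub["category"].tolist() == ["Not specified"]

    def test_death_outcome_counts_as_serious(self, tiny_bundle):
        clean = dedup_bundle(tiny_bundle)
        cases = filter_primary_suspect(clean.drug, {"tisa": ["TISAGENLECLEUCEL"]})
        table = demographics_table(clean, cases)
        serious = table[(table["block"] == "seriousness")
                        & (table["category"] == "Serious")]["count"].item()
        assert serious == 4  # all product cases carry HO
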