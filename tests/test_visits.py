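"""T1/T2 durations, grouping, and automatic group-test selection."""

from datetime import datetime

import numpy as np
import pytest

from edcrowd.scenes import SyntheticVisitConfig, generate_visit_records
from edcrowd.visits import (
    GroupingScheme,
    VisitRecord,
    compare_groups,
    compute_durations,
    group_summary,
    influence_report,
    read_records_csv,
    usable_fraction,
    write_records_csv,
)


def record(receipt="09:00", diagnosis=None, payment=None, dispense=None, **kw):
    def ts(hhmm):
        if hhmm is None:
            return None
        h, m = hhmm.split(":")
        return datetime(2020, 10, 26, int(h), int(m))

    defaults = dict(id="r1", sex="Female", age=30.0, diagnoses=("Respiratory system",))
    defaults.update(kw)
    return VisitRecord(
        t_receipt=ts(receipt),
        t_diagnosis=ts(diagnosis),
        t_payment=ts(payment),
        t_dispense=ts(dispense),
        **defaults,
    )


class TestComputeDurations:
    def test_t2_is_diagnosis_minus_receipt(self):
        d = compute_durations(record(diagnosis="09:37", payment="10:00"))
        assert d.t2_minutes == 37.0

    def test_t1_prefers_dispense_over_payment(self):
        d = compute_durations(record(diagnosis="09:30", payment="10:15", dispense="10:40"))
        assert d.t1_minutes == 100.0

    def test_t1_falls_back_to_payment(self):
        d = compute_durations(record(diagnosis="09:30", payment="10:15"))
        assert d.t1_minutes == 75.0
        assert d.usable

    def test_payment_preference_switch(self):
        d = compute_durations(
            record(diagnosis="09:30", payment="10:15", dispense="10:40"),
            prefer_dispense=False,
        )
        assert d.t1_minutes == 75.0

    def test_missing_diagnosis_is_unusable_not_an_error(self):
        d = compute_durations(record(payment="10:00"))
        assert not d.usable
        assert d.t2_minutes is None

    def test_negative_duration_is_unusable(self):
        d = compute_durations(record(receipt="10:00", diagnosis="09:00", payment="11:00"))
        assert not d.usable

    def test_post_diagnosis_interval(self):
        d = compute_durations(record(diagnosis="09:30", dispense="10:40"))
        assert d.post_diagnosis_minutes == 70.0


class TestUsableFraction:
    def test_all_complete_records(self):
        recs = [record(id=f"r{i}", diagnosis="09:30", payment="10:00") for i in range(5)]
        assert usable_fraction(recs) == (5, 1.0)

    def test_all_missing_records(self):
        recs = [record(id=f"r{i}") for i in range(4)]
        assert usable_fraction(recs) == (0, 0.0)

    def test_survey_proportion(self):
        recs = [record(id=f"u{i}", diagnosis="09:30", payment="10:00") for i in range(3675)]
        recs += [record(id=f"m{i}") for i in range(4717 - 3675)]
        n, frac = usable_fraction(recs)
        assert n == 3675
        assert round(100 * frac, 1) == 77.9

    def test_order_invariance(self):
        recs = [record(id="a", diagnosis="09:30", payment="10:00"), record(id="b")]
        assert usable_fraction(recs)[0] == usable_fraction(recs[::-1])[0]

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            usable_fraction([])


class TestGroupingScheme:
    def test_age_bands_partition_all_ages(self):
        scheme = GroupingScheme()
        for age in [0, 0.5, 1, 2.9, 3, 6, 11.9, 12, 19.9, 20, 59.9, 60, 95]:
            assert scheme.age_band_label(age) in scheme.band_labels()

    def test_twelve_belongs_to_adolescent_band(self):
        assert GroupingScheme().age_band_label(12) == "[12,20)"

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ValueError):
            GroupingScheme(age_bands=((0, 5), (4, float("inf"))))

    def test_uncovered_ages_rejected(self):
        with pytest.raises(ValueError):
            GroupingScheme(age_bands=((0, 5), (5, 60)))


class TestGroupSummary:
    def test_single_record_is_its_whole_level(self):
        summary = group_summary([record(diagnosis="09:30", payment="10:00")])
        sex = summary[summary.factor == "sex"]
        assert list(sex["percent"]) == [100.0]

    def test_counts_sum_to_record_count_per_factor(self):
        recs = generate_visit_records(SyntheticVisitConfig(n_records=300, seed=1))
        summary = group_summary(recs)
        for factor in ("sex", "age_band", "n_diagnoses"):
            assert summary[summary.factor == factor]["count"].sum() == 300
            assert summary[summary.factor == factor]["percent"].sum() == pytest.approx(100.0)

    def test_disease_denominator_is_total_diagnoses(self):
        recs = generate_visit_records(SyntheticVisitConfig(n_records=300, seed=1))
        summary = group_summary(recs)
        n_diag = sum(len(r.diagnoses) for r in recs)
        assert summary[summary.factor == "disease_type"]["count"].sum() == n_diag

    def test_unknown_category_rejected(self):
        scheme = GroupingScheme(categories=("Trauma",))
        with pytest.raises(ValueError):
            group_summary([record(diagnosis="09:30", payment="10:00")], scheme)


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        vals = np.r_[np.arange(20.0), np.arange(20.0)]
        labels = np.r_[np.zeros(20), np.ones(20)]
        res = compare_groups(vals, labels)
        assert res.test == "t-test"
        assert res.p_value > 0.9
        assert not res.significant

    def test_two_sample_power_at_unit_effect(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(100):
            a = rng.normal(0, 1, 200)
            b = rng.normal(1, 1, 200)
            res = compare_groups(np.r_[a, b], np.r_[np.zeros(200), np.ones(200)])
            hits += res.significant
        assert hits >= 99

    def test_skewed_groups_use_kruskal_wallis(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate([rng.lognormal(0, 1.5, 80) for _ in range(3)])
        labels = np.repeat([0, 1, 2], 80)
        assert compare_groups(vals, labels).test == "kruskal-wallis"

    def test_normal_homoscedastic_groups_use_anova(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate([rng.normal(m, 1, 80) for m in (0, 0.2, 0.4)])
        labels = np.repeat([0, 1, 2], 80)
        assert compare_groups(vals, labels).test == "anova"

    def test_heteroscedastic_normal_groups_fall_back_to_kruskal(self):
        rng = np.random.default_rng(3)
        vals = np.concatenate(
            [rng.normal(0, s, 100) for s in (1.0, 1.0, 6.0)]
        )
        labels = np.repeat([0, 1, 2], 100)
        assert compare_groups(vals, labels).test == "kruskal-wallis"

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestInfluenceReport:
    def test_planted_age_effect_flags_age_for_t2(self):
        cfg = SyntheticVisitConfig(n_records=800, effect_age_t2=0.6, seed=3)
        report = influence_report(generate_visit_records(cfg), min_group_size=5)
        row = report[(report.factor == "age_band") & (report.duration == "t2_minutes")]
        assert row["significant"].item()

    def test_report_covers_each_factor_for_both_durations(self):
        cfg = SyntheticVisitConfig(n_records=600, seed=4)
        report = influence_report(generate_visit_records(cfg), min_group_size=5)
        assert set(report.factor) == {"sex", "age_band", "n_diagnoses", "disease_type"}
        assert (report.groupby("factor")["duration"].count() == 2).all()

    def test_null_data_rarely_significant(self):
        sig = 0
        total = 0
        for rep in range(25):
            cfg = SyntheticVisitConfig(n_records=250, seed=100 + rep)
            report = influence_report(generate_visit_records(cfg), min_group_size=5)
            sig += report["significant"].sum()
            total += len(report)
        assert sig / total <= 0.10


def test_records_csv_round_trip(tmp_path):
    recs = generate_visit_records(SyntheticVisitConfig(n_records=40, seed=5))
    write_records_csv(recs, tmp_path / "records.csv")
    loaded = read_records_csv(tmp_path / "records.csv")
    assert len(loaded) == 40
    assert loaded[0].id == recs[0].id
    assert loaded[0].diagnoses == recs[0].diagnoses
    assert loaded[0].t_receipt.replace(microsecond=0) == recs[0].t_receipt.replace(microsecond=0)
    orig_usable = [compute_durations(r).usable for r in recs]
    load_usable = [compute_durations(r).usable for r in loaded]
    assert orig_usable == load_usable
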