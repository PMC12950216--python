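"""Signed-rank test, rank correlation, change summaries, replication report."""

import numpy as np
import pytest

import ctbodycomp.stats as stats_mod
from ctbodycomp.metrics import CompositionRecord
from ctbodycomp.phantom import default_spec, generate_cohort, write_cohort
from ctbodycomp.stats import (
    DegenerateInputError,
    replicate_study,
    spearman,
    summarize_changes,
    wilcoxon_signed_rank,
)

from _oracles import signed_rank_p_enumeration


class TestWilcoxon:
    def test_all_positive_n5_exact(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5])
        assert res.p_value == pytest.approx(2 / 32)
        assert res.method == "exact"
        assert res.statistic == 15.0

    def test_antisymmetric_differences_null_center(self):
        res = wilcoxon_signed_rank([3, -3, 1.5, -1.5, 7, -7])
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "diffs",
        [
            [1, 2, 3],
            [1, 1, -1, 2, 2],  # ties
            [0, 0, 1, -2, 3],  # zeros dropped
            [5, 5, 5, -5, 2, -2, 7],
            [-1, -2, -3, -4, 0.5],
        ],
    )
    def test_exact_matches_sign_flip_enumeration(self, diffs):
        res = wilcoxon_signed_rank(diffs)
        assert res.p_value == pytest.approx(signed_rank_p_enumeration(diffs), abs=1e-12)

    def test_exact_matches_enumeration_random(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            d = rng.integers(-6, 7, size=int(rng.integers(3, 12))).astype(float)
            if not (d != 0).any():
                continue
            assert wilcoxon_signed_rank(d).p_value == pytest.approx(
                signed_rank_p_enumeration(d), abs=1e-12
            )

    def test_agrees_with_scipy_on_tie_free_data(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        rng = np.random.default_rng(9)
        for _ in range(10):
            d = rng.normal(0.5, 1.0, 12)
            ours = wilcoxon_signed_rank(d)
            ref = scipy_wilcoxon(d, alternative="two-sided", method="exact")
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_zeros_dropped(self):
        res = wilcoxon_signed_rank([0.0, 0.0, 1.0, 2.0])
        assert res.n_effective == 2

    def test_all_zero_raises(self):
        with pytest.raises(DegenerateInputError):
            wilcoxon_signed_rank([0.0, 0.0])

    def test_scale_invariance_of_statistic_and_p(self):
        d = np.array([0.3, -1.2, 2.5, 2.5, -0.7, 4.0])
        a = wilcoxon_signed_rank(d)
        b = wilcoxon_signed_rank(1000.0 * d)
        assert a.statistic == b.statistic
        assert a.p_value == b.p_value

    def test_exact_and_normal_agree_at_n20(self):
        """Exact enumeration and the tie-corrected normal approximation agree
        within 0.01 in p over 100 seeded samples."""
        worst = 0.0
        for seed in range(100):
            d = np.random.default_rng(seed).normal(0.3, 1.0, 20)
            exact = wilcoxon_signed_rank(d).p_value
            stats_mod.EXACT_ENUMERATION_MAX_N = 0
            try:
                approx = wilcoxon_signed_rank(d).p_value
            finally:
                stats_mod.EXACT_ENUMERATION_MAX_N = 25
            worst = max(worst, abs(exact - approx))
        assert worst < 0.01

    def test_normal_path_used_above_cutoff(self):
        d = np.random.default_rng(0).normal(0.2, 1.0, 40)
        assert wilcoxon_signed_rank(d).method == "normal"


class TestSpearman:
    def test_perfect_concordance_and_discordance(self):
        x = [1.0, 2.0, 5.0, 9.0]
        y = [0.1, 0.7, 0.8, 3.0]
        assert spearman(x, y)[0] == pytest.approx(1.0)
        assert spearman(x, y[::-1])[0] == pytest.approx(-1.0)

    def test_constant_vector_raises(self):
        with pytest.raises(DegenerateInputError):
            spearman([1, 1, 1], [1, 2, 3])


def _rec(sid, level, phase, sma=100.0, msmd=40.0):
    return CompositionRecord(
        subject_id=sid, level=level, phase=phase,
        sma_cm2=sma, sata_cm2=150.0, vata_cm2=120.0,
        msmd_hu=msmd, msatd_hu=-100.0, mvatd_hu=-90.0,
    )


class TestSummarizeChanges:
    def test_single_subject_percent_change(self):
        recs = [_rec("a", "L3", 0, sma=100.0), _rec("a", "L3", 4, sma=103.5),
                _rec("b", "L3", 0, sma=200.0), _rec("b", "L3", 4, sma=207.0),
                _rec("c", "L3", 0, sma=50.0), _rec("c", "L3", 4, sma=51.75)]
        s = summarize_changes(recs, "SMA", "L3", 4)
        assert s.mode == "percent"
        assert s.per_subject == pytest.approx([3.5, 3.5, 3.5])

    def test_identical_phases_give_zero_changes(self):
        recs = [_rec(s, "L3", p, msmd=42.0) for s in "abc" for p in (0, 2)]
        s = summarize_changes(recs, "MSMD", "L3", 2)
        assert s.mode == "absolute"
        assert s.median == 0.0 and s.mean == 0.0

    def test_five_subject_tukey_summary(self):
        # phase-0 area 100 for everyone; phase-2 values give percent changes
        # [2, 4, 6, 8, 30]: median 6, hinges 4 and 8, upper whisker is the
        # largest point within 8 + 1.5*4 = 14 -> 8; 30 is an outlier
        vals = {"a": 102.0, "b": 104.0, "c": 106.0, "d": 108.0, "e": 130.0}
        recs = [_rec(s, "L1", 0, sma=100.0) for s in vals] + [
            _rec(s, "L1", 2, sma=v) for s, v in vals.items()
        ]
        s = summarize_changes(recs, "SMA", "L1", 2)
        assert s.median == 6.0
        assert (s.q1, s.q3) == (4.0, 8.0)
        assert (s.whisker_low, s.whisker_high) == (2.0, 8.0)
        assert s.mean == pytest.approx(10.0)

    def test_missing_phase_listed_in_exclusions(self):
        recs = [_rec("a", "L3", 0), _rec("a", "L3", 1), _rec("b", "L3", 0)]
        s = summarize_changes(recs, "SMA", "L3", 1)
        assert s.subjects == ("a",)
        assert s.exclusions and s.exclusions[0][0] == "b"

    def test_mean_median_within_range(self):
        rng = np.random.default_rng(5)
        recs = []
        for i in range(12):
            recs.append(_rec(f"s{i}", "L3", 0, sma=100.0))
            recs.append(_rec(f"s{i}", "L3", 3, sma=float(rng.uniform(80, 130))))
        s = summarize_changes(recs, "SMA", "L3", 3)
        assert s.per_subject.min() <= s.mean <= s.per_subject.max()
        assert s.per_subject.min() <= s.median <= s.per_subject.max()


@pytest.fixture(scope="module")
def small_report(tmp_path_factory):
    root = tmp_path_factory.mktemp("replicate")
    spec = default_spec(subject_count=4, seed=3, image_size=160, pixel_spacing=2.5)
    write_cohort(generate_cohort(spec), root / "cohort", compress=False)
    return replicate_study(root / "cohort", root / "report", make_figures=True)


class TestReplicateStudy:
    def test_report_structure(self, small_report):
        # 2 levels x 6 parameters x 10 phase pairs
        assert len(small_report.tests) == 120
        assert len(small_report.records) == 40
        assert len(small_report.regressions) == 30
        assert len(small_report.summaries) == 48
        assert len(small_report.errors) == 0
        assert len(small_report.figure_paths) == 4
        import os

        for p in small_report.figure_paths:
            assert os.path.exists(p)

    def test_density_tests_detect_enhancement(self, small_report):
        """With 4 subjects all showing higher MSMD at phase 4, the signed-rank
        statistic saturates and p hits the exact-test floor 2/2^4."""
        t = small_report.tests
        dens = t[(t.parameter == "MSMD") & (t.phase_a == 0) & (t.phase_b == 4)]
        assert (dens.statistic == 10.0).all()  # all 4 differences positive
        assert np.allclose(dens.p_value, 2 / 16)

    def test_type_one_error_control_under_null(self, tmp_path):
        """With zero injected offsets and static organs, phase-0-vs-4 tests
        are significant at the nominal rate only."""
        significant = total = 0
        for seed in range(3):
            spec = default_spec(
                subject_count=10, seed=seed, image_size=160, pixel_spacing=2.5,
                phase_offsets={(t, p): 0.0 for t in ("muscle", "sat", "vat") for p in range(5)},
                organ_enhancement={p: 160.0 for p in range(5)},
            )
            cohort = generate_cohort(spec)
            from conftest import measure_cohort
            from ctbodycomp.stats import _records_by_subject

            records = measure_cohort(cohort)
            for level in ("L3", "L1"):
                for param in ("SMA", "SATA", "VATA", "MSMD", "MSATD", "MVATD"):
                    by_subj = _records_by_subject(records, param, level)
                    diffs = [v[4] - v[0] for v in by_subj.values()]
                    try:
                        res = wilcoxon_signed_rank(diffs)
                    except DegenerateInputError:
                        continue
                    total += 1
                    significant += res.p_value < 0.05
        assert total >= 30
        assert significant / total <= 0.15
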