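"""Reference ranges, calling rules, review flags and screen arithmetic."""
import numpy as np
import pytest

import abrscreen as abr
from abrscreen.calling import (
    IOFFlag,
    ReferenceRange,
    build_reference_range,
    fraction_pct,
    hit_rate_and_extrapolate,
    iof_flag,
    is_outside,
    min_sls_to_flag,
    review_false_positive,
    rule_mean_deviation,
    rule_outside_fraction,
    screen_fdr,
    waveform_triage,
)
from abrscreen.metrics import IOFCurve
from abrscreen.types import ThresholdProfile


def _profiles(values_by_stim):
    """Build per-mouse profiles from {stimulus: [per-mouse thresholds]}."""
    n = len(next(iter(values_by_stim.values())))
    return [
        ThresholdProfile.from_values({s: v[i] for s, v in values_by_stim.items()})
        for i in range(n)
    ]


FLAT_REF = {"tone:6": ReferenceRange(10.0, 20.0, 45.0, 100)}


class TestReferenceRange:
    def test_degenerate_constant_sample(self):
        rr = build_reference_range([20.0] * 40)
        assert (rr.p2_5, rr.median, rr.p97_5) == (20.0, 20.0, 20.0)

    def test_uniform_grid_closed_form(self):
        """Linear order-statistic interpolation on {1..1000}."""
        rr = build_reference_range(np.arange(1, 1001))
        assert rr.p2_5 == pytest.approx(25.975)
        assert rr.median == pytest.approx(500.5)
        assert rr.p97_5 == pytest.approx(975.025)

    def test_normal_sample_matches_quantiles(self):
        rng = np.random.default_rng(0)
        rr = build_reference_range(rng.normal(20, 5, 2000))
        assert abs(rr.p2_5 - 10.2) < 0.5
        assert abs(rr.p97_5 - 29.8) < 0.5

    def test_underpowered_rejected(self):
        with pytest.raises(ValueError, match="underpowered"):
            build_reference_range(range(19))

    def test_hazen_convention_differs(self):
        rr = build_reference_range(np.arange(1, 1001), convention="hazen")
        assert rr.p2_5 == pytest.approx(25.5)
        assert rr.p97_5 == pytest.approx(975.5)


class TestOutsideFraction:
    def test_three_of_four_fires(self):
        prof = _profiles({"tone:6": [95, 95, 95, 40]})
        frac, fired, direction = rule_outside_fraction(prof, FLAT_REF)
        assert frac["tone:6"] == 0.75 and fired and direction == "elevated"

    def test_one_of_four_does_not_fire(self):
        prof = _profiles({"tone:6": [50, 40, 40, 40]})
        frac, fired, _ = rule_outside_fraction(prof, FLAT_REF)
        assert frac["tone:6"] == 0.25 and not fired

    def test_value_at_bound_counts_inside(self):
        prof = _profiles({"tone:6": [45, 45, 45, 45]})
        frac, fired, direction = rule_outside_fraction(prof, FLAT_REF)
        assert frac["tone:6"] == 0.0 and not fired and direction == "none"

    def test_empty_line_rejected(self):
        with pytest.raises(ValueError):
            rule_outside_fraction([], FLAT_REF)


class TestMeanDeviation:
    @pytest.mark.parametrize(
        "mean,fires", [(60.0, True), (35.0, False), (40.0, True)]  # 40: exactly 20 dB
    )
    def test_deviation_threshold_inclusive(self, mean, fires):
        prof = _profiles({"tone:6": [mean] * 4})
        dev, fired = rule_mean_deviation(prof, FLAT_REF)
        assert dev["tone:6"] == pytest.approx(abs(mean - 20.0))
        assert fired is fires

    def test_monotone_in_uniform_shift(self):
        """Raising every mouse by delta never decreases any deviation once
        the line sits above the control median."""
        base = _profiles({"tone:6": [40, 45, 50, 55]})
        dev0, _ = rule_mean_deviation(base, FLAT_REF)
        shifted = _profiles({"tone:6": [50, 55, 60, 65]})
        dev1, _ = rule_mean_deviation(shifted, FLAT_REF)
        assert dev1["tone:6"] >= dev0["tone:6"]


class TestBonferroni:
    def test_screen_wide_threshold(self):
        assert abr.bonferroni(0.05, 1211) == pytest.approx(4.1e-5, rel=0.02)

    def test_candidate_gene_threshold(self):
        assert abr.bonferroni(0.05, 74) == pytest.approx(6.76e-4, rel=0.005)

    def test_identity(self):
        assert abr.bonferroni(0.05, 1) == 0.05

    @pytest.mark.parametrize("m", [1, 2, 37, 74, 1211])
    def test_product_recovers_alpha(self, m):
        assert abr.bonferroni(0.05, m) * m == pytest.approx(0.05, rel=1e-12)

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            abr.bonferroni(0.05, 0)


class TestIOFFlag:
    def _ref(self, n_sls):
        return {
            ("amp_P1N1", float(sl)): ReferenceRange(1.0, 2.0, 3.0, 100)
            for sl in range(5, 5 * n_sls + 5, 5)
        }

    def _curve(self, n_out, n_sls):
        sls = np.arange(5.0, 5.0 * n_sls + 5.0, 5.0)
        vals = np.full(n_sls, 2.0)
        vals[:n_out] = 4.0  # above the range
        return IOFCurve("amp_P1N1", sls, vals)

    def test_five_of_twelve_fires(self):
        res = iof_flag(self._curve(5, 12), self._ref(12))
        assert res.flag and res.direction == "up" and res.n_outside == 5

    def test_four_of_twelve_does_not(self):
        assert not iof_flag(self._curve(4, 12), self._ref(12)).flag

    def test_ceiling_rule_on_partial_grid(self):
        assert min_sls_to_flag(8) == 4
        assert iof_flag(self._curve(4, 8), self._ref(8)).flag

    def test_no_overlap_rejected(self):
        with pytest.raises(ValueError):
            iof_flag(self._curve(2, 4), {("lat_P1", 5.0): ReferenceRange(0, 1, 2, 50)})


class TestWaveformTriage:
    def _setup(self):
        t = np.linspace(0, 8, 801)
        mean = np.sin(t)
        return t, mean, mean - 0.5, mean + 0.5

    def test_identical_mean_is_negative(self):
        t, mean, lo, hi = self._setup()
        assert not waveform_triage(mean, lo, hi, t, (1.0, 5.0))

    def test_amplitude_collapse_is_positive(self):
        t, mean, lo, hi = self._setup()
        assert waveform_triage(mean * 0.2, lo, hi, t, (1.0, 5.0))

    def test_two_percent_excursion_is_negative(self):
        t, mean, lo, hi = self._setup()
        wobble = mean.copy()
        inside = (t >= 1) & (t <= 5)
        idx = np.flatnonzero(inside)[: int(0.02 * inside.sum())]
        wobble[idx] = hi[idx] + 1.0
        assert not waveform_triage(wobble, lo, hi, t, (1.0, 5.0))

    def test_time_base_mismatch_rejected(self):
        t, mean, lo, hi = self._setup()
        with pytest.raises(ValueError):
            waveform_triage(mean[:-1], lo[:-1], hi[:-1], t, (1.0, 5.0))


class TestReview:
    REF = {"tone:6": ReferenceRange(10.0, 20.0, 30.0, 100)}

    def test_single_outlier_cancels_rules(self):
        """One mouse at ceiling drags the mean over the 20-dB rule; removing
        it cancels both rules, so the line is flagged."""
        prof = _profiles({"tone:6": [95, 25, 25, 25]})
        _, fired = rule_mean_deviation(prof, self.REF)
        assert fired  # mean 42.5, deviation 22.5
        flags = review_false_positive(prof, "tone:6", self.REF)
        assert "single_outlier" in flags

    def test_tight_line_no_flags(self):
        prof = _profiles({"tone:6": [60, 60, 60, 60]})
        assert review_false_positive(prof, "tone:6", self.REF) == set()

    def test_excess_variability(self):
        prof = _profiles({"tone:6": [95, 90, 25, 20]})
        flags = review_false_positive(prof, "tone:6", self.REF)
        assert "excess_variability" in flags

    def test_single_mouse_rejected(self):
        prof = _profiles({"tone:6": [95]})
        with pytest.raises(ValueError):
            review_false_positive(prof, "tone:6", self.REF)


class TestScreenArithmetic:
    @pytest.mark.parametrize(
        "n_false,expected", [(6, 0.50), (12, 0.99), (0, 0.00)]
    )
    def test_fdr(self, n_false, expected):
        assert screen_fdr(n_false, 1211) == expected

    def test_hit_rate(self):
        rate, remaining = hit_rate_and_extrapolate(38, 1211, 20_000)
        assert rate == 3.14
        assert remaining == 590

    def test_boundary_genome(self):
        assert hit_rate_and_extrapolate(38, 1211, 1211) == (3.14, 0)

    def test_het_screened_fraction(self):
        assert fraction_pct(356, 1211) == 29.40

    def test_invalid(self):
        with pytest.raises(ValueError):
            hit_rate_and_extrapolate(38, 1211, 1000)
        with pytest.raises(ValueError):
            screen_fdr(5, 0)


def test_control_self_coverage(control_reference):
    """Per-stimulus outside fractions of the control cohort against its own
    grid-level range stay below the nominal 5% (ties at the percentile
    bounds count inside, and grid mass concentrates on the bounds)."""
    controls, ref = control_reference
    profiles = [m.thresholds for m in controls]
    fractions, fired, _ = rule_outside_fraction(profiles, ref)
    assert not fired
    for s, f in fractions.items():
        assert f <= 0.05 + 0.01
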