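"""Per-allele trend test, covariate adjustment and gene-window scanning."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import abrscreen as abr
from abrscreen.association import (
    MarkerWindow,
    assoc_significance,
    log_adjust_trait,
    per_allele_test,
    window_scan,
)


class TestLogAdjust:
    def test_constant_trait_zero_residuals(self):
        res = log_adjust_trait(np.full(20, 30.0))
        assert np.allclose(res, 0.0, atol=1e-12)

    def test_pure_covariate_signal_projected_out(self):
        """A trait equal to exp(covariate effect) leaves zero residuals."""
        rng = np.random.default_rng(0)
        sex = rng.integers(0, 2, 50)
        raw = np.exp(1.0 + 0.3 * sex)
        res = log_adjust_trait(raw, pd.DataFrame({"sex": sex}))
        assert np.allclose(res, 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_covariates(self):
        rng = np.random.default_rng(1)
        cov = pd.DataFrame(
            {"sex": rng.integers(0, 2, 200), "nuisance": rng.integers(0, 3, 200)}
        )
        raw = np.exp(rng.normal(3.0, 0.3, 200))
        res = log_adjust_trait(raw, cov)
        for col in cov:
            assert abs(np.corrcoef(res, cov[col])[0, 1]) < 1e-10

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            log_adjust_trait(np.array([1.0, -2.0]))


class TestPerAllele:
    def test_perfect_signal(self):
        g = np.tile([0, 1, 2], 10)
        assert per_allele_test(g, g.astype(float)) < 1e-10

    def test_monomorphic_is_missing(self):
        assert np.isnan(per_allele_test(np.zeros(20, dtype=int), np.arange(20.0)))

    def test_matches_one_df_f_test(self):
        """The slope t-test p equals the 1-df regression F-test p."""
        rng = np.random.default_rng(3)
        g = rng.binomial(2, 0.3, 300)
        y = 0.1 * g + rng.normal(0, 1, 300)
        p_slope = per_allele_test(g, y)
        r = np.corrcoef(g, y)[0, 1]
        f = r**2 * (300 - 2) / (1 - r**2)
        p_f = stats.f.sf(f, 1, 298)
        assert p_slope == pytest.approx(p_f, abs=1e-10)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            per_allele_test(np.array([0, 1, 2]), np.arange(3.0))

    def test_null_type_one_error_short(self):
        """Permutation-scale sanity check of calibration (full 10,000-rep
        calibration runs in the acceptance checks)."""
        rej = 0
        for i in range(500):
            coh = abr.generate_assoc_cohort(200, n_markers=1, maf=0.3, seed=i)
            adj = log_adjust_trait(coh.trait_raw["4kHz"], coh.covariates)
            rej += per_allele_test(coh.genotypes[:, 0], adj) <= 0.05
        assert 0.03 <= rej / 500 <= 0.075


class TestWindowScan:
    WINDOW = MarkerWindow("g", 1_000_000, 1_050_000, flank_bp=100_000)

    def test_single_marker_inside_gene(self):
        res = window_scan(np.array([1_010_000]), np.array([0.01]), self.WINDOW)
        assert res.min_p_in_gene == res.min_p_in_window == 0.01

    def test_markers_only_in_flank(self):
        res = window_scan(
            np.array([920_000, 1_140_000]), np.array([0.2, 0.002]), self.WINDOW
        )
        assert res.min_p_in_gene is None
        assert res.min_p_in_window == 0.002

    def test_flank_boundary_inclusive(self):
        res = window_scan(np.array([900_000]), np.array([0.03]), self.WINDOW)
        assert res.min_p_in_window == 0.03
        out = window_scan(np.array([899_999]), np.array([0.03]), self.WINDOW)
        assert out.min_p_in_window is None

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            window_scan(np.array([5, 3]), np.array([0.1, 0.2]), self.WINDOW)

    def test_enlarging_flank_never_raises_min_p(self):
        rng = np.random.default_rng(7)
        pos = np.sort(rng.integers(800_000, 1_300_000, 40))
        pv = rng.random(40)
        prev = np.inf
        for flank in (0, 50_000, 100_000, 200_000):
            w = MarkerWindow("g", 1_000_000, 1_050_000, flank_bp=flank)
            res = window_scan(pos, pv, w)
            if res.min_p_in_window is not None:
                assert res.min_p_in_window <= prev
                prev = res.min_p_in_window


class TestSignificance:
    def test_candidate_gene_threshold(self):
        thr = 0.05 / (37 * 2)
        assert thr == pytest.approx(6.76e-4, rel=1e-3)
        assert assoc_significance(0.000213)  # an observed in-gene minimum
        assert not assoc_significance(0.01)

    def test_power_monotone_in_beta(self):
        """Rejection rate grows with the per-allele effect size."""
        rates = []
        for beta in (0.0, 0.3, 1.0):
            hits = 0
            for i in range(40):
                coh = abr.generate_assoc_cohort(
                    300, n_markers=3, maf=0.3, beta_per_allele=beta,
                    causal_index=1, seed=1000 + i,
                )
                adj = log_adjust_trait(coh.trait_raw["4kHz"], coh.covariates)
                hits += per_allele_test(coh.genotypes[:, 1], adj) < 6.76e-4
            rates.append(hits / 40)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] >= 0.95
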