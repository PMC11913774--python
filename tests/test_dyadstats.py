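"""Design construction, mixed-model contracts, trim rule, FDR."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from cardiosync.dyadstats import (DyadDesign, FormulaSpec, build_dyad_design,
                                  fdr_adjust, fit_mixed_model, lag_group_contrast,
                                  saturated_then_trim)
from cardiosync.hrv_behavior import behavioral_table, hrv_table
from cardiosync.surrogate import real_synchrony_table
from cardiosync.synchrony import SynchronyConfig
from cardiosync.synthetic import StudyConfig, generate_study

CFG = SynchronyConfig(prewhiten_method="ar_diff")


@pytest.fixture(scope="module")
def small_study():
    return generate_study(StudyConfig(n_dyads=10, block_duration_s=40,
                                      baseline_duration_s=40, seed=21))


@pytest.fixture(scope="module")
def design(small_study):
    real = real_synchrony_table(small_study, CFG)
    hrv = hrv_table(small_study)
    beh = behavioral_table(small_study.trials_table())
    return build_dyad_design(small_study, real, hrv, beh)


class TestBuildDesign:
    def test_sum_absdiff_exact(self, small_study, design):
        d = small_study.dyads[0]
        s1, s2 = d.social_anxiety["s1"], d.social_anxiety["s2"]
        mu, sd = design.scalers["sum_social_anxiety"]
        row = design.table[design.table["dyad"] == d.dyad_id].iloc[0]
        assert row["sum_social_anxiety"] == pytest.approx(((s1 + s2) - mu) / sd, abs=1e-10)
        mu2, sd2 = design.scalers["absdiff_social_anxiety"]
        assert row["absdiff_social_anxiety"] == pytest.approx(
            (abs(s1 - s2) - mu2) / sd2, abs=1e-10)

    def test_row_count_ten_dyads(self, design):
        assert len(design.table) == 10 * 16

    def test_standardization(self, design):
        for col in design.sum_terms + ["grasp_diff_ms"]:
            assert design.table[col].mean() == pytest.approx(0.0, abs=1e-9)
            assert design.table[col].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_novelty_coding(self, design):
        assert set(design.table["novelty_old"].unique()) == {0.0, 1.0}


class TestFdrAdjust:
    def test_hand_computed(self):
        assert np.allclose(fdr_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_equal(self):
        assert fdr_adjust([0.2]) == pytest.approx([0.2])
        assert np.allclose(fdr_adjust([0.04, 0.04, 0.04]), [0.04, 0.04, 0.04])

    def test_matches_statsmodels_on_random_vectors(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 1, rng.integers(2, 30))
            mine = fdr_adjust(p)
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(mine, ref, atol=1e-12)

    def test_monotone_after_sorting(self, rng):
        p = rng.uniform(0, 1, 25)
        adj = fdr_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_invalid_values(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])


class TestFitMixedModel:
    def _noise_design(self, rng, n_dyads=15, n_blocks=8, beta=0.0):
        rows = []
        for d in range(n_dyads):
            u = rng.normal(0, 0.5)
            x_d = rng.normal(0, 1)
            for b in range(n_blocks):
                x = rng.normal(0, 1)
                rows.append({"dyad": f"d{d}", "x": x, "x_dyad": x_d,
                             "outcome": beta * x + u + rng.normal(0, 1)})
        return pd.DataFrame(rows)

    def test_type_i_error_calibrated(self):
        rej = 0
        reps = 120
        for rep in range(reps):
            rng = np.random.default_rng(rep)
            tab = self._noise_design(rng)
            rep_ = fit_mixed_model(tab, FormulaSpec("outcome", ["x"]))
            p = rep_.params.set_index("name").loc["x", "p"]
            rej += p < 0.05
        assert 0.01 <= rej / reps <= 0.10

    def test_slope_recovery(self):
        rng = np.random.default_rng(5)
        tab = self._noise_design(rng, n_dyads=40, n_blocks=12, beta=2.0)
        rep = fit_mixed_model(tab, FormulaSpec("outcome", ["x"]))
        est = rep.params.set_index("name").loc["x", "estimate"]
        assert est == pytest.approx(2.0, rel=0.1)
        assert rep.null_comparison["p"] < 1e-6

    def test_unknown_predictor_raises(self):
        tab = self._noise_design(np.random.default_rng(0))
        with pytest.raises(ValueError, match="unknown"):
            fit_mixed_model(tab, FormulaSpec("outcome", ["nope"]))

    def test_report_invariants(self, design):
        rep = fit_mixed_model(design, FormulaSpec("outcome", ["novelty_old",
                                                             "sum_social_anxiety"]))
        pr = rep.params
        assert ((pr["p_fdr"] >= pr["p"] - 1e-12).all())
        assert ((pr["ci_low"] <= pr["estimate"]) & (pr["estimate"] <= pr["ci_high"])).all()
        assert 0 <= rep.r2["marginal"] <= rep.r2["conditional"] <= 1


class TestSaturatedThenTrim:
    def _design_with_outcome(self, rng, sum_beta=0.0, absdiff_beta=0.0,
                             novelty_beta=0.0, n_dyads=20):
        rows = []
        for d in range(n_dyads):
            s1, s2 = rng.normal(0, 1, 2)
            u = rng.normal(0, 0.3)
            for b in range(8):
                nov = float(b % 2 == 0)
                y = (sum_beta * (s1 + s2) + absdiff_beta * abs(s1 - s2)
                     + novelty_beta * nov + u + rng.normal(0, 1))
                rows.append({"dyad": f"d{d}", "block": f"b{b}", "outcome": y,
                             "novelty_old": nov, "block_type_lf": float(b >= 4),
                             "sum_score": s1 + s2, "absdiff_score": abs(s1 - s2)})
        tab = pd.DataFrame(rows)
        for c in ("sum_score", "absdiff_score"):
            tab[c] = (tab[c] - tab[c].mean()) / tab[c].std(ddof=0)
        return DyadDesign(table=tab, scalers={}, sum_terms=["sum_score"],
                          absdiff_terms=["absdiff_score"],
                          between_terms=["novelty_old", "block_type_lf"])

    def test_sum_only_data_trims(self):
        # with a null ABSDIFF effect the theoretical trim rate is 1 - alpha
        trims = 0
        reps = 30
        for rep in range(reps):
            rng = np.random.default_rng(200 + rep)
            d = self._design_with_outcome(rng, sum_beta=0.8)
            out = saturated_then_trim(d)
            trims += out.trimmed
        assert trims / reps >= 0.9

    def test_absdiff_effect_keeps_saturated(self):
        kept = 0
        for rep in range(10):
            rng = np.random.default_rng(300 + rep)
            d = self._design_with_outcome(rng, absdiff_beta=1.5)
            out = saturated_then_trim(d)
            kept += not out.trimmed
        assert kept >= 9

    def test_novelty_sign_recovered(self):
        rng = np.random.default_rng(77)
        d = self._design_with_outcome(rng, novelty_beta=-1.0, sum_beta=0.5)
        out = saturated_then_trim(d)
        est = out.params.set_index("name").loc["novelty_old", "estimate"]
        assert est < 0


class TestLagGroupContrast:
    def test_long_table_shape(self, small_study):
        real = real_synchrony_table(small_study, CFG)
        long = lag_group_contrast(real)
        assert len(long) == len(real) * 3
        assert set(long["lag_group"]) == {"negative", "zero", "positive"}

    def test_missing_columns_raise(self):
        with pytest.raises(ValueError):
            lag_group_contrast(pd.DataFrame({"dyad": [], "block": []}))
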