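"""Mixed-model suite, BH-FDR, and model comparison."""

import itertools
import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import natisc as n
from natisc.stats import compare_models, fdr_bh, fit_condition_model, fit_lme

from conftest import single_condition_design


def bh_oracle(pvals, m=None):
    """Direct step-up definition, independent of the implementation."""
    m = m or len(pvals)
    idx = sorted(range(len(pvals)), key=lambda i: pvals[i])
    adj = [None] * len(pvals)
    running = 1.0
    for rank in range(len(pvals), 0, -1):
        i = idx[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = min(running, 1.0)
    return adj


class TestFdrBH:
    def test_hand_computed_example(self):
        assert fdr_bh([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert fdr_bh([0.37]) == [0.37]

    def test_sorted_input_gives_nondecreasing_output(self):
        p = np.sort(np.random.default_rng(0).uniform(size=20))
        adj = fdr_bh(p)
        assert all(a <= b + 1e-15 for a, b in zip(adj, adj[1:]))

    def test_matches_oracle_on_all_orderings_of_small_sets(self):
        base = [0.001, 0.01, 0.04, 0.2, 0.5]
        for perm in itertools.permutations(base, 4):
            assert fdr_bh(list(perm)) == pytest.approx(bh_oracle(list(perm)), abs=1e-14)

    def test_matches_statsmodels_on_random_inputs(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 12))
            ours = fdr_bh(p)
            theirs = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(ours, theirs, atol=1e-12)

    def test_external_family_size_and_validation(self):
        assert fdr_bh([0.01], n=5) == [0.05]
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])
        with pytest.raises(ValueError):
            fdr_bh([0.5, 0.5], n=1)


class TestConditionModel:
    def test_sign_pattern_on_paper_template(self, paper_isc):
        fit = fit_condition_model(paper_isc)
        assert fit.coef("+M/+L")[0] > 0
        assert fit.coef("-M/-L")[0] < 0
        assert fit.reference_level == "+M/-L"
        assert fit.fit_method == "REML"

    def test_equal_tracking_gives_null_type_effects(self):
        from natisc.synthdata import ConditionSpec, SimDesign, simulate_timecourses

        conds = [
            ConditionSpec(f"c{i}", t, 332.0, "visual", 12)
            for i, t in enumerate(["+M/-L", "+M/-L", "+M/+L", "+M/+L", "-M/-L", "-M/-L"])
        ]
        d = SimDesign(
            conditions=conds,
            tracking_strength={"+M/-L": 0.1, "+M/+L": 0.1, "-M/-L": 0.1},
            frois=("f0", "f1"),
            participation={c.name: tuple(f"P{i}" for i in range(12)) for c in conds},
            seed=31,
        )
        isc = n.compute_isc_table(n.preprocess(simulate_timecourses(d)))
        fit = fit_condition_model(isc)
        for term in ("+M/+L", "-M/-L"):
            beta, se, _ = fit.coef(term)
            assert abs(beta) < 3 * se

    def test_reference_change_shifts_coefficients_consistently(self, paper_isc):
        f1 = fit_condition_model(paper_isc, reference="+M/-L")
        f2 = fit_condition_model(paper_isc, reference="+M/+L")
        b_pp = f1.coef("+M/+L")[0]
        assert f2.coef("Intercept")[0] == pytest.approx(
            f1.coef("Intercept")[0] + b_pp, abs=1e-5
        )
        assert f2.coef("+M/-L")[0] == pytest.approx(-b_pp, abs=1e-5)

    def test_single_condition_type_reduces_to_intercept(self):
        d = single_condition_design(a=0.2, n=8, T=100, seed=2, n_frois=2)
        from natisc.synthdata import simulate_timecourses

        isc = n.compute_isc_table(n.preprocess(simulate_timecourses(d)))
        fit = fit_condition_model(isc)
        assert fit.terms["term"].tolist() == ["Intercept"]

    def test_matches_lme4_on_identical_data(self, paper_isc, tmp_path):
        """Independent oracle: lme4's REML fit of the same crossed design."""
        data_path = tmp_path / "isc.tsv"
        paper_isc.to_csv(data_path, sep="\t", index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            'suppressMessages(library(lme4))\n'
            f'd <- read.delim("{data_path}")\n'
            'd$condition_type <- relevel(factor(d$condition_type), ref="+M/-L")\n'
            'm <- lmer(z ~ condition_type + (1|froi) + (1|participant) + (1|condition),'
            ' data=d, REML=TRUE)\n'
            'co <- summary(m)$coefficients\n'
            'cat(co[,1], co[,2], logLik(m), sep="\\n")\n'
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        vals = [float(v) for v in out.stdout.split()]
        r_betas, r_ses, r_loglik = vals[0:3], vals[3:6], vals[6]
        fit = fit_condition_model(paper_isc)
        ours = {t: fit.coef(t) for t in ("Intercept", "-M/-L", "+M/+L")}
        # lme4 orders levels alphabetically after the reference
        np.testing.assert_allclose(
            [ours["Intercept"][0], ours["-M/-L"][0], ours["+M/+L"][0]], r_betas, atol=2e-4
        )
        np.testing.assert_allclose(
            [ours["Intercept"][1], ours["-M/-L"][1], ours["+M/+L"][1]], r_ses, atol=2e-4
        )
        assert fit.loglik == pytest.approx(r_loglik, abs=0.01)


class TestPerConditionModels:
    def test_recoding_yields_six_levels_and_matched_fdr(self, paper_isc):
        fits, summary = n.per_condition_suite(paper_isc)
        zero_fit = fits["zero"]
        assert len(zero_fit.terms) == 6  # cell means for six condition types
        stims = {"AnimShort", "SilentFilm", "IntentShapes", "SoundEffectStory"}
        assert set(summary["condition"]) == stims
        assert len(summary) == 12  # 4 stimuli x 3 reference comparisons
        assert (summary["p_fdr"] >= summary["p"] - 1e-15).all()

    def test_zero_reference_on_null_data_gives_near_zero_betas(self):
        from natisc.synthdata import ConditionSpec, SimDesign, simulate_timecourses

        conds = [
            ConditionSpec("a1", "+M/-L", 232.0, "visual", 10),
            ConditionSpec("a2", "+M/+L", 232.0, "visual", 10),
            ConditionSpec("a3", "-M/-L", 232.0, "visual", 10),
        ]
        d = SimDesign(
            conditions=conds,
            tracking_strength={"+M/-L": 0.0, "+M/+L": 0.0, "-M/-L": 0.0},
            frois=("f0",),
            participation={c.name: tuple(f"P{i}" for i in range(10)) for c in conds},
            seed=17,
        )
        isc = n.compute_isc_table(n.preprocess(simulate_timecourses(d)))
        fit = n.fit_per_condition_model(isc, reference="zero")
        for _, row in fit.terms.iterrows():
            assert abs(row["beta"]) < 3 * row["se"] + 0.05


class TestPerFroiAndInteraction:
    def test_per_froi_returns_one_fit_per_froi_with_fdr(self, paper_isc):
        fits = n.fit_per_froi_model(paper_isc)
        assert set(fits) == {"IFGorb", "IFG", "MFG", "AntTemp", "PostTemp"}
        for f in fits.values():
            assert "p_fdr" in f.terms.columns
            assert (f.terms["p_fdr"] >= f.terms["p"] - 1e-15).all()

    def test_silenced_froi_shows_no_tracking(self):
        from natisc.synthdata import simulate_timecourses

        d = single_condition_design(a=0.3, n=15, T=200, seed=8, n_frois=2)
        d.froi_modifiers = {"froi1": 0.0}
        isc = n.compute_isc_table(n.preprocess(simulate_timecourses(d)))
        fits = n.fit_per_froi_model(isc)
        b0, se0, _ = fits["froi0"].coef("Intercept")
        b1, se1, _ = fits["froi1"].coef("Intercept")
        assert b0 > 3 * se0
        assert abs(b1) < 3 * se1 + 0.05

    def test_interaction_model_term_count(self, paper_isc):
        fit = n.fit_interaction_model(paper_isc)
        # 5 fROI intercepts + 5 x (3 - 1) contrasts
        assert len(fit.terms) == 5 + 5 * 2
        assert not any(t == "Intercept" for t in fit.terms["term"])


class TestCompareModels:
    def _two_fits(self, paper_isc):
        a = fit_condition_model(paper_isc, reml=False)
        data = paper_isc.copy()
        rng = np.random.default_rng(0)
        noise = pd.Series(rng.standard_normal(data["condition"].nunique()),
                          index=sorted(data["condition"].unique()))
        data["junk"] = data["condition"].map(noise)
        b = fit_lme(
            data[data["condition_type"] != "rest"],
            'C(condition_type, Treatment("+M/-L")) + junk',
            vc_factors=["froi", "participant", "condition"],
            formula_id="with_junk", reference_level="+M/-L", reml=False,
        )
        return a, b

    def test_identical_fits_compare_to_zero(self, paper_isc):
        a = fit_condition_model(paper_isc, reml=False)
        lrt = compare_models(a, a, nested=True)
        assert (lrt["chi2"], lrt["df"], lrt["p"]) == (0.0, 0, 1.0)
        assert compare_models(a, a, nested=False)["delta_aic"] == 0.0

    def test_lrt_on_nested_fits(self, paper_isc):
        a, b = self._two_fits(paper_isc)
        out = compare_models(a, b, nested=True)
        assert out["df"] == 1
        assert 0 <= out["p"] <= 1
        # chi2[1] critical value at alpha = .05 reproduced by the p computation
        from scipy.stats import chi2

        assert chi2.sf(3.841, 1) == pytest.approx(0.05, abs=1e-3)

    def test_reml_fits_rejected_for_lrt(self, paper_isc):
        a = fit_condition_model(paper_isc, reml=True)
        with pytest.raises(ValueError, match="ML"):
            compare_models(a, a, nested=True)

    def test_row_mismatch_rejected(self, paper_isc):
        a = fit_condition_model(paper_isc, reml=False)
        b = fit_condition_model(paper_isc.iloc[:-5], reml=False)
        with pytest.raises(ValueError, match="identical rows"):
            compare_models(a, b, nested=True)

    def test_aic_definition_under_ml(self, paper_isc):
        a = fit_condition_model(paper_isc, reml=False)
        assert a.aic == pytest.approx(2 * a.n_params - 2 * a.loglik, abs=1e-10)


class TestSingleLevelFactor:
    def test_single_level_random_factor_dropped_with_warning(self, paper_isc):
        sub = paper_isc[paper_isc["froi"] == "IFG"]
        with pytest.warns(UserWarning, match="single level"):
            fit = fit_lme(
                sub, 'C(condition_type, Treatment("+M/-L"))',
                vc_factors=["froi", "participant", "condition"],
                formula_id="x", reference_level="+M/-L",
            )
        assert "froi" not in fit.vc_estimates
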