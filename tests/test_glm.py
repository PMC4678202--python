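"""Joint GLM, drop-one F-tests and backward elimination.

The independent oracle is an explicit pseudo-inverse normal-equations
solver (tests/oracles.py); statsmodels OLS provides a second, external
cross-check on a fixed instance.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import genosets as g
from conftest import random_encoding
from oracles import drop_one_f, ols_pinv, one_hot_design


def _sim_context(seed, n=120, genes=2, noise=1.0, effect=0.0):
    rng = np.random.default_rng(seed)
    encs = [random_encoding(rng, n, n_snps=rng.integers(1, 3), gene=f"G{j}")
            for j in range(genes)]
    encs = [e for e in encs if e.informative]
    y = rng.normal(0, noise, n)
    if effect and encs:
        y = y + effect * encs[0].codes
    return y, encs


class TestFitJointModel:
    def test_matches_pinv_oracle_on_random_instances(self):
        for seed in range(10):
            y, encs = _sim_context(seed, n=150, genes=3, effect=0.5)
            fit = g.fit_joint_model(y, encs)
            X, meta = one_hot_design(encs)
            ora = ols_pinv(y, X)
            assert fit.r2 == pytest.approx(ora["r2"], abs=1e-8)
            assert fit.adj_r2 == pytest.approx(ora["adj_r2"], abs=1e-8)
            assert fit.p == ora["p"]
            for _, row in fit.gene_tests.iterrows():
                F, df1, df2, P = drop_one_f(y, X, meta, row["gene"])
                assert row["F"] == pytest.approx(F, abs=1e-8)
                assert (row["df1"], row["df2"]) == (df1, df2)
                assert row["p_value"] == pytest.approx(P, abs=1e-8)

    def test_perfect_fit_reports_unit_r2(self):
        rng = np.random.default_rng(1)
        enc = random_encoding(rng, 60, n_snps=1, gene="G")
        y = 2.0 + 1.5 * enc.codes  # exact function of the factor, no noise
        fit = g.fit_joint_model(y, [enc])
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.adj_r2 == pytest.approx(1.0, abs=1e-12)
        assert 0 < fit.gene_tests["p_value"].iloc[0] <= 1e-30

    def test_intercept_only_model_has_zero_r2(self):
        y = np.random.default_rng(2).normal(size=40)
        fit = g.fit_joint_model(y, [])
        assert fit.r2 == pytest.approx(0.0, abs=1e-12)
        assert fit.p == 0 and len(fit.gene_tests) == 0

    def test_adjusted_r2_never_exceeds_r2(self):
        for seed in range(8):
            y, encs = _sim_context(seed, n=90, genes=2, effect=0.3)
            fit = g.fit_joint_model(y, encs)
            assert fit.adj_r2 <= fit.r2 + 1e-12

    def test_duplicated_gene_is_fully_aliased(self):
        rng = np.random.default_rng(3)
        enc = random_encoding(rng, 100, n_snps=1, gene="A")
        twin = g.FactorEncoding(gene="B", levels=enc.levels,
                                counts=enc.counts, codes=enc.codes,
                                pooled_labels=())
        y = rng.normal(size=100) + 0.5 * enc.codes
        fit = g.fit_joint_model(y, [enc, twin])
        row = fit.gene_tests.set_index("gene").loc["B"]
        assert row["df1"] == 0 and row["p_value"] == 1.0
        assert any(a.startswith("B:") for a in fit.aliased)

    def test_degenerate_inputs_raise(self):
        rng = np.random.default_rng(4)
        enc = random_encoding(rng, 50, gene="G")
        with pytest.raises(g.DegenerateInputError, match="zero variance"):
            g.fit_joint_model(np.ones(50), [enc])
        tiny = g.FactorEncoding(gene="G", levels=tuple("abcdefghij"),
                                counts=(1,) * 10,
                                codes=np.arange(10) % 10,
                                pooled_labels=())
        with pytest.raises(g.RankError, match="min_level_count"):
            g.fit_joint_model(np.random.default_rng(5).normal(size=10), [tiny])

    def test_agrees_with_statsmodels_on_fixed_instance(self):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(6)
        e1 = random_encoding(rng, 200, n_snps=2, gene="A")
        e2 = random_encoding(rng, 200, n_snps=1, gene="B")
        y = rng.normal(size=200) + 0.4 * e2.codes
        fit = g.fit_joint_model(y, [e1, e2])
        df = pd.DataFrame({"y": y,
                           "A": pd.Categorical.from_codes(
                               e1.codes, list(e1.levels)),
                           "B": pd.Categorical.from_codes(
                               e2.codes, list(e2.levels))})
        sm_fit = smf.ols("y ~ C(A) + C(B)", data=df).fit()
        assert fit.r2 == pytest.approx(sm_fit.rsquared, abs=1e-10)
        assert fit.adj_r2 == pytest.approx(sm_fit.rsquared_adj, abs=1e-10)


class TestGeneFTest:
    def test_single_two_level_gene_f_equals_t_squared(self):
        # F of a 2-level factor == squared pooled two-sample t statistic
        rng = np.random.default_rng(7)
        codes = (rng.uniform(size=80) < 0.4).astype(int)
        enc = g.FactorEncoding(gene="G", levels=("0", "1"),
                               counts=(int((codes == 0).sum()),
                                       int((codes == 1).sum())),
                               codes=codes, pooled_labels=())
        y = rng.normal(size=80) + 0.6 * codes
        F, df1, df2, P = g.gene_f_test(y, [enc], "G")
        t = stats.ttest_ind(y[codes == 1], y[codes == 0]).statistic
        assert F == pytest.approx(t**2, abs=1e-10)
        assert (df1, df2) == (1, 78)

    def test_unknown_gene_raises(self):
        rng = np.random.default_rng(8)
        enc = random_encoding(rng, 50, gene="G")
        with pytest.raises(KeyError):
            g.gene_f_test(rng.normal(size=50), [enc], "H")


class TestBackwardElimination:
    def test_retained_genes_all_significant_and_trace_consistent(self):
        for seed in range(6):
            y, encs = _sim_context(seed, n=200, genes=4, effect=0.4)
            trace = g.backward_eliminate(y, encs, threshold=0.05)
            if trace.final.genes:
                assert (trace.final.gene_tests["p_value"] <= 0.05).all()
            # one gene removed per step, each above threshold at removal
            assert (trace.steps["p_value"] > 0.05).all()
            assert trace.steps["gene"].is_unique

    def test_threshold_one_removes_nothing(self):
        y, encs = _sim_context(0, n=150, genes=3)
        trace = g.backward_eliminate(y, encs, threshold=1.0)
        assert len(trace.steps) == 0
        assert trace.final.genes == tuple(e.gene for e in encs)

    def test_elimination_is_deterministic(self):
        y, encs = _sim_context(9, n=150, genes=4, effect=0.3)
        t1 = g.backward_eliminate(y, encs)
        t2 = g.backward_eliminate(y, encs)
        pd.testing.assert_frame_equal(t1.steps, t2.steps)
        assert t1.final.genes == t2.final.genes

    def test_removal_never_increases_r2(self):
        y, encs = _sim_context(10, n=150, genes=4, effect=0.3)
        full = g.fit_joint_model(y, encs)
        trace = g.backward_eliminate(y, encs)
        r2s = [full.r2] + trace.steps["r2_after"].tolist()
        assert all(a >= b - 1e-12 for a, b in zip(r2s, r2s[1:]))

    def test_boundary_p_exactly_at_threshold_is_retained(self):
        # removal requires P strictly greater than the threshold
        y, encs = _sim_context(11, n=150, genes=2, effect=0.4)
        fit = g.fit_joint_model(y, encs)
        thr = float(fit.gene_tests["p_value"].max())
        trace = g.backward_eliminate(y, encs, threshold=thr)
        assert len(trace.steps) == 0


class TestEffects:
    def test_reference_level_effect_is_zero_and_rest_match_oracle(self):
        y, encs = _sim_context(12, n=180, genes=2, effect=0.5)
        fit = g.fit_joint_model(y, encs)
        summ = g.estimate_combination_effects(fit)
        X, meta = one_hot_design(encs)
        beta = ols_pinv(y, X)["beta"]
        ref = summ.effects[summ.effects["is_reference"]]
        assert (ref["estimate"] == 0).all()
        est = summ.effects[~summ.effects["is_reference"]]
        for (gene, level), b in zip(meta[1:], beta[1:]):
            row = est[(est["gene"] == gene) & (est["level"] == level)]
            assert row["estimate"].iloc[0] == pytest.approx(b, abs=1e-8)
        assert summ.n_positive + summ.n_negative <= len(est)

    def test_minor_allele_dose_effects_are_positive_in_expectation(self):
        # all minor alleles increase the trait -> non-reference contrasts
        # against the all-zero reference are predominantly positive
        pos, tot = 0, 0
        for seed in range(50):
            rng = np.random.default_rng(100 + seed)
            geno = rng.binomial(2, 0.2, size=(250, 2)).astype(float)
            frame = pd.DataFrame(geno, columns=["s1", "s2"])
            comp = g.build_composite(frame, g.GeneSnpSet("G", ("s1", "s2")))
            enc = g.encode_factor(comp, 5)
            if enc.reference != "0-0":
                continue
            dose = geno.sum(axis=1)
            y = dose + rng.normal(0, 0.5, 250)
            fit = g.fit_joint_model(y, [enc])
            est = fit.effects[~fit.effects["is_reference"]]["estimate"].dropna()
            pos += int((est > 0).sum())
            tot += len(est)
        assert tot > 0 and pos / tot >= 0.9
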