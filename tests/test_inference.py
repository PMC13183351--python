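"""Entropy descriptives and the hierarchical Bernoulli model."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import entropy as scipy_entropy

from roleprobe.entropy import describe_dataset, entropy_ml
from roleprobe.errors import ConvergenceError
from roleprobe.hier import (DeltaPSummary, HierModelSpec, PosteriorDraws,
                            _Posterior, build_model_data,
                            counterfactual_delta_p,
                            fit_hierarchical_bernoulli,
                            posterior_predictive_check, simulate_records)
from roleprobe.synth import default_register_spec, generate_corpus


class TestEntropyML:
    @pytest.mark.parametrize("counts,expected", [
        ({"a": 1, "b": 1, "c": 1, "d": 1}, 2.0),
        ({"a": 7}, 0.0),
        ({"a": 2, "b": 1, "c": 1}, 1.5),
    ])
    def test_closed_form_values(self, counts, expected):
        assert entropy_ml(counts) == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            k = int(rng.integers(1, 12))
            counts = {f"c{i}": int(rng.integers(1, 50)) for i in range(k)}
            ours = entropy_ml(counts)
            ref = scipy_entropy(np.array(list(counts.values()), float),
                                base=2)
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_all_zero_counts_raise(self):
        with pytest.raises(ValueError):
            entropy_ml({"a": 0, "b": 0})

    def test_bounds(self):
        h = entropy_ml({"a": 5, "b": 3, "c": 2})
        assert 0 <= h <= np.log2(3)


class TestDescribeDataset:
    def test_single_lemma_register_zero_argument_entropy(self):
        spec = default_register_spec(
            "Z", pronoun_prob=0.0, filler_prob=0.0,
            number_dist={"SG": 1.0, "PL": 0.0},
            concentration={"A": 1e-4, "P": 1e-4})
        # single case frame so the single P lemma has a single surface form
        spec.lexicon.verbs = [v for v in spec.lexicon.verbs
                              if v.p_case == "ACC"]
        ds = generate_corpus(spec, 300, seed=1)
        rep = describe_dataset(ds)
        assert rep.argument_entropy["A"] == pytest.approx(0.0, abs=1e-9)
        assert rep.argument_entropy["P"] == pytest.approx(0.0, abs=1e-9)

    def test_deterministic_order_zero_word_order_entropy(self, avp_corpus):
        _spec, ds = avp_corpus
        rep = describe_dataset(ds)
        assert rep.word_order_entropy == pytest.approx(0.0, abs=1e-12)

    def test_case_entropy_present_for_russian_like(self, small_corpus):
        spec, ds = small_corpus
        rep = describe_dataset(ds, spec.paradigm)
        assert set(rep.case_entropy) == {"A", "P"}
        assert rep.case_entropy["P"] > rep.case_entropy["A"] - 1e-9


def _manual_fit(records, beta_values, cds_label="CDS"):
    """PosteriorDraws with hand-set coefficients and negligible random
    effects — an analytic stand-in for a fitted model."""
    spec = HierModelSpec(cds_label=cds_label)
    data = build_model_data(records, spec)
    post = _Posterior(data, spec)
    theta = np.zeros((2, 10, post.dim))
    for name, val in beta_values.items():
        theta[:, :, data.coef_names.index(name)] = val
    theta[:, :, post.k: post.k + post.n_scales] = -30.0  # log sigma ~ 0
    diag = pd.DataFrame({"parameter": data.coef_names,
                         "rhat": 1.0, "ess": 20.0})
    return PosteriorDraws(theta=theta, posterior_=post, data=data,
                          spec=spec, diagnostics=diag)


class TestCounterfactualDeltaP:
    @pytest.fixture(scope="class")
    def records(self):
        return simulate_records(n_sentences=40, per_cell=1, seed=0)

    def test_fixed_logits_closed_form(self, records):
        """Register logit 2.0 (CDS) vs 1.0 (ADS) for every sentence gives
        DeltaP = sigmoid(2) - sigmoid(1) exactly."""
        fit = _manual_fit(records, {"intercept": 1.0, "register": 1.0})
        dp = counterfactual_delta_p(fit, {"role": "P"})
        expected = expit(2.0) - expit(1.0)
        assert dp.mean == pytest.approx(expected, abs=1e-9)
        assert dp.ci_low == pytest.approx(expected, abs=1e-9)

    def test_zero_register_effect_gives_zero(self, records):
        fit = _manual_fit(records, {"intercept": 0.7})
        dp = counterfactual_delta_p(fit, {})
        assert dp.mean == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetric_under_register_relabelling(self, records):
        """Swapping the register labels (and reparameterising the same
        data-generating model accordingly) flips DeltaP's sign exactly."""
        fit = _manual_fit(records, {"intercept": 0.3, "register": 0.8})
        swapped_records = records.assign(
            register=records["register"].map({"CDS": "ADS", "ADS": "CDS"}))
        # equivalent model under swapped coding: baseline absorbs the
        # effect, the indicator coefficient is negated
        swapped = _manual_fit(swapped_records,
                              {"intercept": 1.1, "register": -0.8})
        a = counterfactual_delta_p(fit, {"role": "P"})
        b = counterfactual_delta_p(swapped, {"role": "P"})
        assert a.mean == pytest.approx(-b.mean, abs=1e-12)

    def test_empty_cell_raises(self, records):
        fit = _manual_fit(records, {})
        with pytest.raises(ValueError):
            counterfactual_delta_p(fit, {"role": "Q"})

    def test_delta_p_bounded(self, records):
        fit = _manual_fit(records, {"register": 50.0})
        dp = counterfactual_delta_p(fit, {})
        assert -1.0 <= dp.mean <= 1.0


class TestModelData:
    def test_single_register_rejected(self):
        rec = simulate_records(n_sentences=10, seed=0)
        rec = rec[rec.register == "CDS"]
        with pytest.raises(ValueError):
            build_model_data(rec, HierModelSpec())

    def test_rank_deficient_design_rejected(self):
        rec = simulate_records(n_sentences=10, seed=0)
        rec["dup"] = rec["register"]  # duplicates the register column
        with pytest.raises(ValueError):
            build_model_data(rec, HierModelSpec(extra_fixed=("dup",)))

    def test_diagnostics_always_present(self):
        rec = simulate_records(n_sentences=40, per_cell=1, seed=1)
        fit = fit_hierarchical_bernoulli(rec, draws=150, warmup=200,
                                         seed=3, allow_nonconverged=True)
        assert {"rhat", "ess"} <= set(fit.diagnostics.columns)
        assert len(fit.diagnostics) >= len(fit.data.coef_names)


class TestSmallFits:
    """Cheap sampler checks; the full-scale recovery lives in the
    acceptance suite."""

    def test_fixed_effect_matches_mle_without_random_effects(self):
        """With random-effect scales simulated at ~0, the posterior mean
        of the register effect agrees with the frequentist MLE."""
        import statsmodels.api as sm

        rec = simulate_records(n_sentences=150, per_cell=2,
                               register_effect=0.8, sd_split=0.01,
                               sd_split_role=0.01, sd_sent=0.01,
                               sd_sent_role=0.01, seed=5)
        fit = fit_hierarchical_bernoulli(rec, draws=400, warmup=400, seed=2,
                                         allow_nonconverged=True)
        data = fit.data
        glm = sm.GLM(data.y, data.X,
                     family=sm.families.Binomial()).fit()
        j = data.coef_names.index("register")
        post_mean = float(fit.fixed_effect("register").mean())
        assert post_mean == pytest.approx(glm.params[j], abs=0.25)

    def test_ppc_covers_observed_cells(self):
        rec = simulate_records(n_sentences=120, per_cell=2,
                               register_effect=0.5, seed=8)
        fit = fit_hierarchical_bernoulli(rec, draws=300, warmup=350, seed=4,
                                         allow_nonconverged=True)
        ppc = posterior_predictive_check(fit, seed=0)
        assert ppc["covered"].mean() >= 0.75

    def test_nonconvergence_raises_when_not_allowed(self):
        rec = simulate_records(n_sentences=30, per_cell=1, seed=9)
        with pytest.raises(ConvergenceError):
            fit_hierarchical_bernoulli(rec, draws=40, warmup=30, seed=1,
                                       rhat_threshold=1.0001)
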