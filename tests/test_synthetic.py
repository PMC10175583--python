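"""Synthetic cohort generator: chain structure, signal model, effect links."""

import numpy as np
import pytest
from scipy import stats

from napqeeg.recording import Hypnogram, STATES
from napqeeg.spectral import band_power
from napqeeg.staging import compute_macrostructure
from napqeeg.synthetic import (
    Effect,
    SubjectProfile,
    TransitionParams,
    default_state_model,
    generate_cohort,
    generate_hypnogram,
    synthesize_signals,
)
from tests.conftest import one_state_hypnogram


class TestSubjectProfile:
    def test_valid_profile(self):
        SubjectProfile("d1", 12.0, 18, 40.0, 90.0, 50.0, 17.0)

    @pytest.mark.parametrize("field,value", [
        ("cades", 96), ("cades", -1), ("age", 0.0),
        ("memory", 130.0), ("inhibitory", 101.0), ("detour", -5.0),
    ])
    def test_invariants_enforced(self, field, value):
        kwargs = dict(subject_id="d1", age=12.0, cades=18, memory=40.0,
                      inhibitory=90.0, detour=50.0, gaze=17.0)
        kwargs[field] = value
        with pytest.raises(ValueError):
            SubjectProfile(**kwargs)

    def test_missing_detour_allowed(self):
        p = SubjectProfile("d1", 12.0, 18, 40.0, 90.0, None, 17.0)
        assert np.isnan(p.as_dict()["detour"])


class TestGenerateHypnogram:
    def test_duration_not_multiple_of_epoch_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            generate_hypnogram(7201.0)

    def test_two_hours_gives_2400_epochs(self):
        assert len(generate_hypnogram(7200.0, seed=1)) == 2400

    def test_absorbing_chain_stays_in_wake(self):
        tp = TransitionParams(base={})  # all self-transitions are 1
        hyp = generate_hypnogram(7200.0, tp, seed=3)
        assert len(hyp) == 2400 and (hyp.labels == "W").all()

    def test_rem_entry_from_wake_rejected(self):
        tp = TransitionParams(base={("W", "R"): 0.01})
        with pytest.raises(ValueError, match="ordered entry"):
            generate_hypnogram(300.0, tp)

    def test_unreachable_state_with_rates_rejected(self):
        # N has outgoing rates but no entry path from W
        tp = TransitionParams(base={("W", "D"): 0.02, ("N", "R"): 0.01})
        with pytest.raises(ValueError, match="unreachable"):
            generate_hypnogram(300.0, tp)

    def test_rem_only_follows_nrem(self):
        hyp = generate_hypnogram(7200.0, seed=7)
        labels = hyp.labels
        r_starts = np.flatnonzero((labels[1:] == "R") & (labels[:-1] != "R")) + 1
        assert len(r_starts) > 0
        assert all(labels[i - 1] == "N" for i in r_starts)


class TestSynthesizeSignals:
    def test_all_nrem_is_delta_dominant(self, one_state_recordings):
        from napqeeg.pipeline import subject_qeeg
        from napqeeg.staging import select_analysis_epochs

        hyp = one_state_hypnogram("N", 90)
        q = subject_qeeg(one_state_recordings["N"],
                         select_analysis_epochs(hyp))
        spec = q["power"][("Fz", "N")]
        delta = band_power(spec, "delta")
        assert delta > band_power(spec, "beta")
        assert delta > max(band_power(spec, b)
                           for b in ("theta", "alpha", "sigma", "gamma"))

    def test_rem_atonia_below_wake_tone(self, one_state_recordings):
        rms = {
            s: float(np.sqrt(np.mean(one_state_recordings[s].signals["EMG"] ** 2)))
            for s in ("W", "R")
        }
        assert rms["R"] < 0.1 * rms["W"]

    def test_unknown_state_rejected(self):
        hyp = one_state_hypnogram("W", 10)
        hyp.labels = hyp.labels.copy()
        object.__setattr__(hyp, "labels", np.array(["W"] * 9 + ["X"]))
        with pytest.raises(ValueError):
            synthesize_signals(hyp, seed=0)

    def test_zero_shared_weight_gives_chance_coherence(self):
        from napqeeg.pipeline import subject_qeeg
        from napqeeg.staging import select_analysis_epochs

        model = default_state_model()
        for key in model.pair_msc:
            model.pair_msc[key] = 0.0
        hyp = one_state_hypnogram("W", 14)  # 12 interior epochs, K=60
        rec = synthesize_signals(hyp, model, seed=9)
        q = subject_qeeg(rec, select_analysis_epochs(hyp))
        coh = q["coherence"][("F3-F4", "W")]
        expected = 1.0 / coh.n_windows
        assert abs(coh.msc.mean() - expected) < 0.5 * expected

    def test_model_invariants_validated(self):
        model = default_state_model()
        model.states["W"].band_amps["delta"] = 100.0  # beats NREM delta
        with pytest.raises(ValueError, match="NREM delta"):
            synthesize_signals(one_state_hypnogram("W", 5), model, seed=0)


class TestGenerateCohort:
    def test_determinism_bit_identical(self):
        a = generate_cohort(n=4, seed=42, duration_h=0.1)
        b = generate_cohort(n=4, seed=42, duration_h=0.1)
        for sa, sb in zip(a, b):
            assert sa.profile == sb.profile
            assert np.array_equal(sa.hypnogram.labels, sb.hypnogram.labels)
            assert np.array_equal(sa.hypnogram.artifact, sb.hypnogram.artifact)
            for ch in sa.recording.signals:
                assert np.array_equal(sa.recording.signals[ch],
                                      sb.recording.signals[ch])

    def test_covariates_within_published_ranges(self):
        c = generate_cohort(n=100, seed=5, with_signals=False)
        cov = c.covariates_frame()
        assert cov["age"].between(10.4, 16.2).all()
        assert cov["cades"].between(0, 70).all()
        assert cov["memory"].between(0, 120).all()
        assert cov["inhibitory"].between(13, 100).all()
        assert cov["detour"].dropna().between(0, 100).all()
        assert cov["gaze"].between(1.3, 60).all()

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError, match="at least 3"):
            generate_cohort(n=2, with_signals=False)

    def test_undefined_response_rejected(self):
        with pytest.raises(ValueError, match="undefined response"):
            generate_cohort(n=5, effects=[Effect("age", "power:Oz:N:delta", 0.5)],
                            with_signals=False)

    def test_duration_range_varies_lengths(self):
        c = generate_cohort(n=8, seed=2, duration_range_h=(1.01, 2.0),
                            with_signals=False)
        lengths = {len(s.hypnogram) for s in c}
        assert len(lengths) > 1
        assert all(1212 <= n <= 2400 for n in lengths)

    def test_infeasible_combined_effects_rejected(self):
        effs = [Effect("age", "pct_nrem", 0.9), Effect("cades", "pct_nrem", 0.9)]
        with pytest.raises(ValueError, match="infeasible"):
            generate_cohort(n=5, effects=effs, with_signals=False)


def _recovered_rho(n, seed, effects):
    c = generate_cohort(n=n, effects=effects, seed=seed, with_signals=False)
    cov = c.covariates_frame()
    nrem = [compute_macrostructure(s.hypnogram).pct_nrem for s in c]
    return stats.spearmanr(cov["cades"], nrem).statistic


class TestEffectInjection:
    def test_cades_nrem_sign_recovered_across_seeds(self):
        """A -0.55 dementia-score link to NREM% yields a negative empirical
        rank correlation in >= 95 % of seeds at n=200."""
        effects = [Effect("cades", "pct_nrem", -0.55)]
        neg = sum(_recovered_rho(200, seed, effects) < 0 for seed in range(50))
        assert neg >= 48  # 95% of 50 seeds

    def test_effect_monotonicity(self):
        """Stronger requested effects recover stronger median correlations."""
        medians = []
        for rho in (-0.2, -0.45, -0.7):
            effects = [Effect("cades", "pct_nrem", rho)]
            vals = [_recovered_rho(100, s, effects) for s in range(12)]
            medians.append(np.median(np.abs(vals)))
        assert medians[0] < medians[1] < medians[2]


def test_null_macro_screen_calibration():
    """Without injected effects the macrostructure-covariate Spearman family
    rejects at ~5 %: the fraction of p<0.05 over >= 200 cohorts stays inside
    the binomial 99 % band."""
    from napqeeg.screening import spearman_matrix
    from napqeeg.pipeline import MACRO_VARIABLES

    n_cohorts, n = 200, 28
    hits = total = 0
    for seed in range(n_cohorts):
        c = generate_cohort(n=n, effects=[], seed=10_000 + seed,
                            with_signals=False)
        cov = c.covariates_frame()
        macro = np.array([
            [getattr(compute_macrostructure(s.hypnogram), v) for v in MACRO_VARIABLES]
            for s in c
        ])
        for name in cov.columns.drop("subject_id"):
            _, p, _ = spearman_matrix(macro, cov[name].to_numpy())
            ok = ~np.isnan(p)
            hits += int((p[ok] < 0.05).sum())
            total += int(ok.sum())
    frac = hits / total
    band = 2.576 * np.sqrt(0.05 * 0.95 / total)
    # p-values are discrete-ish and the family is correlated; the band uses
    # the nominal binomial s.e. which is what the calibration claim states
    assert abs(frac - 0.05) < band + 0.01
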