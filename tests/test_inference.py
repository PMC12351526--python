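"""Fitting, BIC scoring, and random-effects model selection."""

import numpy as np
import pandas as pd
import pytest

from motifteach import inference, models, synth
from motifteach.inference import AlphaFitter, bic, log_model_evidence


@pytest.fixture(scope="module")
def reduced_fitter(reduced_space):
    return AlphaFitter(reduced_space, grid=np.round(np.arange(0, 4.0001, 0.1), 4))


def _simulate(space, family, seed, n_teachers=5, n_villages=None, alpha=None):
    n_villages = n_villages or len(space.hypotheses)
    cfg = synth.SynthConfig(
        n_villages=n_villages, n_teachers=n_teachers, teacher_family=family,
        alpha=alpha, master_seed=seed,
    )
    villages = synth.generate_villages(n_villages, space, seed)
    return synth.simulate_teachers(villages, space, cfg)


class TestTrialLoading:
    def test_roundtrip(self, reduced_space):
        df, _ = _simulate(reduced_space, "strong", seed=0)
        trials = inference.load_teacher_trials(df, reduced_space)
        assert len(trials) == len(df)
        back = inference.trials_to_frame(trials)
        assert set(back.columns) == set(df.columns)

    def test_inconsistent_response_rejected(self, reduced_space):
        df = pd.DataFrame(
            [{"participant_id": "T0", "village_id": "V0",
              "motif1": "00", "motif2": "01", "motif3": "10",
              "response": "111111"}]
        )
        with pytest.raises(ValueError, match="not consistent"):
            inference.load_teacher_trials(df, reduced_space)


class TestTrialLikelihood:
    def test_strong_sampling_loglik_is_log_m(self, full_space):
        P = models.strong_sampling(full_space.C)
        h = ("11", "000", "001")
        j = full_space.col(h)
        m = full_space.C[:, j].sum()
        t = inference.TeacherTrial("T0", "V0", h, "0000000111")
        assert inference.trial_log_likelihood(t, P, full_space) == pytest.approx(
            -np.log(m)
        )

    def test_zero_probability_gives_minus_inf(self, full_space):
        P = np.zeros_like(full_space.C, dtype=float) + 1e-300
        P[0, :] = 1.0
        t = inference.TeacherTrial("T0", "V0", ("11", "000", "001"), "0000000111")
        P[full_space.row("0000000111"), :] = 0.0
        assert inference.trial_log_likelihood(t, P, full_space) == -np.inf


class TestBIC:
    def test_formula(self):
        # 18 villages, 10 consistent necklaces each, zero parameters
        ll = -18 * np.log(10)
        assert bic(ll, 0, 18) == pytest.approx(2 * 18 * np.log(10))
        assert bic(ll, 0, 18) == pytest.approx(82.893, abs=1e-3)

    def test_parameter_penalty(self):
        ll = -30.0
        assert bic(ll, 1, 18) - bic(ll, 0, 18) == pytest.approx(np.log(18))

    def test_evidence_is_minus_half_bic(self):
        class F:
            bic = 82.893
        assert log_model_evidence(F()) == pytest.approx(-41.4465)

    def test_validation(self):
        with pytest.raises(ValueError):
            bic(-1.0, 0, 0)


class TestFitAlpha:
    def test_recovers_generating_alpha_on_reduced_space(
        self, reduced_space, reduced_fitter
    ):
        df, truth = _simulate(
            reduced_space, "pedagogical", seed=5, n_teachers=3, alpha=1.0
        )
        trials = inference.load_teacher_trials(df, reduced_space)
        for pid in df.participant_id.unique():
            tt = [t for t in trials if t.participant_id == pid]
            fit = inference.fit_alpha(tt, reduced_fitter)
            assert fit.family == "pedagogical" and fit.k == 1
            assert 0.0 <= fit.alpha_hat <= 4.0
            assert np.isfinite(fit.bic)

    def test_uniform_responses_give_small_alpha(self, full_space):
        # responses drawn uniformly from each village's consistent set
        # are exactly strong sampling, i.e. alpha = 0
        fitter = AlphaFitter(full_space, grid=np.round(np.arange(0, 2.0001, 0.1), 4))
        df, _ = _simulate(full_space, "strong", seed=2, n_teachers=1, n_villages=180)
        trials = inference.load_teacher_trials(df, full_space)
        fit = inference.fit_alpha(trials, fitter)
        assert fit.alpha_hat <= 0.1

    def test_deterministic(self, reduced_space, reduced_fitter):
        df, _ = _simulate(reduced_space, "pedagogical", seed=7, n_teachers=1, alpha=2.0)
        trials = inference.load_teacher_trials(df, reduced_space)
        f1 = inference.fit_alpha(trials, reduced_fitter)
        f2 = inference.fit_alpha(trials, reduced_fitter)
        assert f1 == f2

    def test_boundary_flagged(self, full_space):
        # the teacher probability of "0000000111" for {000,11,001} is
        # nondecreasing in alpha, so repeating it as the only response
        # drives the fit to the top of a short grid
        fitter = AlphaFitter(full_space, grid=np.round(np.arange(0, 1.0001, 0.25), 4))
        t = inference.TeacherTrial("T0", "V0", ("11", "000", "001"), "0000000111")
        fit = inference.fit_alpha([t] * 6, fitter)
        assert fit.boundary and fit.alpha_hat == fitter.grid[-1]

    def test_refinement_never_worse_than_grid(self, reduced_space, reduced_fitter):
        df, _ = _simulate(reduced_space, "pedagogical", seed=9, n_teachers=1, alpha=1.3)
        trials = inference.load_teacher_trials(df, reduced_space)
        coarse = inference.fit_alpha(trials, reduced_fitter, refine=False)
        fine = inference.fit_alpha(trials, reduced_fitter, refine=True)
        assert fine.log_likelihood >= coarse.log_likelihood


class TestFitParticipant:
    def test_strong_family_has_no_parameters(self, reduced_space):
        df, _ = _simulate(reduced_space, "strong", seed=1, n_teachers=1)
        trials = inference.load_teacher_trials(df, reduced_space)
        fit = inference.fit_participant(trials, "strong", reduced_space)
        assert fit.k == 0 and fit.alpha_hat is None
        assert fit.bic == pytest.approx(-2 * fit.log_likelihood)

    def test_heuristic_families_fit(self, reduced_space):
        df, _ = _simulate(reduced_space, "strong", seed=3, n_teachers=1)
        trials = inference.load_teacher_trials(df, reduced_space)
        K = np.linspace(1, 3, len(reduced_space.necklaces))
        for fam, pname in [("lr_heuristic", "lr_weight"),
                           ("simplicity_heuristic", "simplicity_penalty")]:
            fit = inference.fit_participant(
                trials, fam, reduced_space, complexity_scores=K
            )
            assert fit.k == 1 and pname in fit.params
            assert np.isfinite(fit.log_likelihood)

    def test_biased_pedagogical_beats_plain_on_lr_data(self, reduced_space):
        # teacher who always emits an LR-readable necklace for each village
        lr = models.lr_bias_matrix(reduced_space.necklaces, reduced_space.hypotheses)
        spec = models.TeacherModelSpec("pedagogical_lr", alpha=1.0, lr_weight=50.0)
        T = models.variant_teacher(reduced_space.C, spec, lr_indicator=lr)
        rng = np.random.default_rng(0)
        trials = []
        for j, h in enumerate(reduced_space.hypotheses):
            d = reduced_space.necklaces[rng.choice(len(T), p=T[:, j])]
            trials.append(inference.TeacherTrial("T0", f"V{j}", h, d))
        fit_lr = inference.fit_participant(trials, "pedagogical_lr", reduced_space)
        fitter = AlphaFitter(reduced_space, grid=np.round(np.arange(0, 4.0001, 0.1), 4))
        fit_plain = inference.fit_alpha(trials, fitter)
        assert fit_lr.log_likelihood >= fit_plain.log_likelihood


class TestBMS:
    def test_symmetric_evidence(self):
        ev = np.zeros((10, 2))
        res = inference.random_effects_bms(ev, ["a", "b"], seed=0)
        assert res.protected_exceedance == pytest.approx([0.5, 0.5], abs=0.02)
        # closed form for identical evidences at alpha0=1:
        # F1 - F0 = N ln2 - ln G(N+2) + 2 ln G(N/2+1); BOR = 1/(1+exp(.))
        from scipy.special import gammaln
        N = 10
        f_diff = N * np.log(2) - gammaln(N + 2) + 2 * gammaln(N / 2 + 1)
        assert res.bayesian_omnibus_risk == pytest.approx(
            1 / (1 + np.exp(f_diff)), abs=1e-6
        )

    def test_null_risk_grows_with_sample_under_identical_evidence(self):
        bors = [
            inference.random_effects_bms(np.zeros((n, 2)), seed=0,
                                         n_samples=10_000).bayesian_omnibus_risk
            for n in (4, 16, 64, 256)
        ]
        assert all(b2 > b1 for b1, b2 in zip(bors, bors[1:]))
        assert bors[-1] > 0.9

    def test_dominant_family(self):
        ev = np.zeros((30, 2))
        ev[:, 1] = 10.0
        res = inference.random_effects_bms(ev, ["a", "b"], seed=0)
        assert res.protected_exceedance[1] >= 0.99
        assert res.frequencies[1] > 0.9

    def test_single_participant_small_difference_protected(self):
        ev = np.array([[0.0, 0.1]])
        res = inference.random_effects_bms(ev, ["a", "b"], seed=0)
        assert res.bayesian_omnibus_risk > 0.5
        assert abs(res.protected_exceedance[0] - 0.5) < 0.1

    def test_outputs_normalized(self):
        rng = np.random.default_rng(1)
        ev = rng.normal(size=(12, 4))
        res = inference.random_effects_bms(ev, list("abcd"), seed=2)
        assert res.frequencies.sum() == pytest.approx(1.0)
        assert res.exceedance.sum() == pytest.approx(1.0, abs=1e-3)
        assert res.protected_exceedance.sum() == pytest.approx(1.0, abs=1e-3)
        assert ((res.protected_exceedance >= 0) & (res.protected_exceedance <= 1)).all()
        assert 0.0 <= res.bayesian_omnibus_risk <= 1.0

    def test_duplicating_participants_keeps_frequencies_lowers_bor(self):
        # clearly non-uniform model use: 12 of 15 participants favour
        # family a by 3 log-units, so more data disfavour the null
        ev = np.zeros((15, 3))
        ev[:12, 0] = 3.0
        ev[12:, 1] = 3.0
        r1 = inference.random_effects_bms(ev, list("abc"), seed=4)
        r2 = inference.random_effects_bms(np.vstack([ev, ev]), list("abc"), seed=4)
        assert np.abs(r1.frequencies - r2.frequencies).max() < 0.05
        assert r2.bayesian_omnibus_risk < r1.bayesian_omnibus_risk

    def test_minus_inf_evidence_allowed_nan_rejected(self):
        ev = np.array([[0.0, -np.inf], [0.0, -1.0]])
        res = inference.random_effects_bms(ev, ["a", "b"], seed=0)
        assert res.frequencies[0] > res.frequencies[1]
        with pytest.raises(ValueError):
            inference.random_effects_bms(np.array([[0.0, np.nan]]), seed=0)
        with pytest.raises(ValueError):
            inference.random_effects_bms(np.array([[-np.inf, -np.inf]]), seed=0)
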