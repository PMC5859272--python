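"""Tests for the binned birth–death likelihood and (N, lambda) fitting."""

import numpy as np
import pandas as pd
import pytest
import warnings

from cryptdrift import DriftParams, make_niche
from cryptdrift.cohort_synthesis import ArmDesign, CohortDesign, run_neutral_cohort
from cryptdrift.drift_inference import (
    IdentifiabilityWarning,
    binned_loglik,
    compare_arms,
    fit_drift,
)
from cryptdrift.errors import ParameterError

POINT_MASS_MEAN = 1e-9  # labelling mean so small that n0 = 1 almost surely


def records_frame(rows):
    return pd.DataFrame(rows, columns=["mouse_id", "arm", "day", "eighths"])


def recovery_design(seed, n_stem=16, rate=0.1, mice=4, crypts=100):
    params = DriftParams(n_stem=n_stem, replacement_rate=rate)
    half = n_stem // 2
    layout = make_niche(half, n_stem - half)
    return CohortDesign(
        arms=(ArmDesign(name="vehicle", params=params, layout=layout),),
        timepoints=(4.0, 7.0, 10.0, 14.0, 21.0),
        mice_per_arm=mice,
        crypts_per_mouse=crypts,
        labelling_mean=POINT_MASS_MEAN,
        seed=seed,
    )


class TestBinnedLoglik:
    def test_empty_dataset_is_zero(self):
        assert binned_loglik(records_frame([]), 8, 0.5) == 0.0

    def test_day_zero_point_mass_gives_zero_loglik(self):
        # a single-cell clone scored at day 0 in its own bin has probability 1
        rows = [("m0", "vehicle", 0.0, 1)]
        ll = binned_loglik(
            records_frame(rows), 16, 0.5, labelling_mean=POINT_MASS_MEAN
        )
        assert ll == pytest.approx(0.0, abs=1e-9)

    def test_matches_uniformised_path_enumeration(self):
        # independent oracle on N=4: sum over all size paths via uniformisation
        n, lam, t = 4, 0.35, 2.0
        rate = 2 * lam  # constant total stepping rate of the interior states
        q = np.zeros((5, 5))
        for i in (1, 2, 3):
            q[i, i + 1] = lam
            q[i, i - 1] = lam
            q[i, i] = -rate
        jump = np.eye(5) + q / rate
        p_t = np.zeros((5, 5))
        term = np.eye(5)
        log_w = -rate * t
        for k in range(80):
            p_t += np.exp(log_w + k * np.log(rate * t) - sum(np.log(i) for i in range(1, k + 1))) * term
            term = term @ jump
        from scipy.stats import poisson

        m = POINT_MASS_MEAN  # same zero-truncated labelling model, truncated at N
        w = poisson.pmf(np.arange(1, 5), m)
        w[-1] += poisson.sf(4, m)
        start = np.concatenate([[0.0], w / w.sum()])
        probs_size = start @ p_t
        # eighths bins on N=4: sizes (0,1,2,3,4) -> bins (0,2,4,6,8)
        bin_prob = {0: probs_size[0], 2: probs_size[1], 4: probs_size[2],
                    6: probs_size[3], 8: probs_size[4]}
        rows = [("m0", "vehicle", t, e) for e in (0, 2, 2, 4, 8)]
        expected = sum(np.log(bin_prob[e]) for _, _, _, e in rows)
        ll = binned_loglik(
            records_frame(rows),
            n,
            lam,
            labelling_mean=POINT_MASS_MEAN,
            condition_on_survival=False,
        )
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_survival_conditioning_renormalises(self):
        n, lam, t = 4, 0.35, 2.0
        rows_surv = [("m0", "vehicle", t, 2)]
        ll_cond = binned_loglik(
            records_frame(rows_surv), n, lam, labelling_mean=POINT_MASS_MEAN
        )
        ll_raw = binned_loglik(
            records_frame(rows_surv),
            n,
            lam,
            labelling_mean=POINT_MASS_MEAN,
            condition_on_survival=False,
        )
        assert ll_cond > ll_raw  # dividing by P(surv) < 1 raises the likelihood

    def test_negative_day_rejected(self):
        with pytest.raises(ParameterError):
            binned_loglik(records_frame([("m", "a", -1.0, 2)]), 8, 0.5)


class TestFitDrift:
    def test_parameter_recovery_default_design(self):
        # 2,000 single-cell clones, five timepoints, truth (N=16, lambda=0.1)
        ds = run_neutral_cohort(recovery_design(seed=2024))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", IdentifiabilityWarning)
            res = fit_drift(ds, labelling_mean=POINT_MASS_MEAN,
                            condition_on_survival=False)
        assert abs(res.n_stem_hat - 16) <= 2
        assert abs(res.replacement_rate_hat - 0.1) <= 0.025
        assert res.rate_ci[0] <= res.replacement_rate_hat <= res.rate_ci[1]
        assert res.n_stem_hat in res.n_support

    def test_truth_beats_ridge_alternative(self):
        # loglik at the truth exceeds loglik at (2N, lambda/2) in >= 90% of
        # replicate datasets
        wins = 0
        reps = 50
        for r in range(reps):
            ds = run_neutral_cohort(recovery_design(seed=5000 + r, crypts=40))
            at_truth = binned_loglik(
                ds, 16, 0.1, labelling_mean=POINT_MASS_MEAN,
                condition_on_survival=False,
            )
            at_ridge = binned_loglik(
                ds, 32, 0.05, labelling_mean=POINT_MASS_MEAN,
                condition_on_survival=False,
            )
            wins += at_truth >= at_ridge
        assert wins >= 0.9 * reps

    def test_single_timepoint_warns_but_returns_surface(self):
        rows = [("m0", "a", 7.0, e) for e in (2, 4, 4, 6, 8, 0)]
        with pytest.warns(IdentifiabilityWarning):
            res = fit_drift(
                records_frame(rows), n_grid=range(4, 10),
                labelling_mean=1.2, n_rate_grid=12,
            )
        assert not res.loglik_surface.empty

    def test_degenerate_all_fixed_data_hits_fast_corner(self):
        # every clone fixed at every day: likelihood favours small N / high
        # rate; the fit must not crash and the corner must be in support
        rows = [("m0", "a", d, 8) for d in (4.0, 7.0) for _ in range(30)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", IdentifiabilityWarning)
            res = fit_drift(
                records_frame(rows), n_grid=range(4, 17),
                labelling_mean=1.2, n_rate_grid=15,
            )
        assert res.n_stem_hat == 4
        assert res.replacement_rate_hat > 1.0

    def test_empty_dataset_rejected(self):
        with pytest.raises(ParameterError):
            fit_drift(records_frame([]))


class TestCompareArms:
    @staticmethod
    def _two_arm_dataset(n_a, n_b, seed):
        frames = []
        for name, n_stem in (("armA", n_a), ("armB", n_b)):
            params = DriftParams(n_stem=n_stem, replacement_rate=0.1)
            half = n_stem // 2
            design = CohortDesign(
                arms=(
                    ArmDesign(
                        name=name,
                        params=params,
                        layout=make_niche(half, n_stem - half),
                    ),
                ),
                timepoints=(4.0, 7.0, 10.0, 14.0, 21.0),
                mice_per_arm=4,
                crypts_per_mouse=100,
                labelling_mean=POINT_MASS_MEAN,
                seed=seed,
            )
            frames.append(run_neutral_cohort(design).records)
        return pd.concat(frames, ignore_index=True)

    _FIT_KW = dict(
        n_grid=range(4, 25),
        labelling_mean=POINT_MASS_MEAN,
        condition_on_survival=False,
        n_boot=20,
        n_rate_grid=15,
    )

    def test_single_arm_rejected(self):
        df = self._two_arm_dataset(16, 16, seed=1)
        with pytest.raises(ParameterError, match="two arms"):
            compare_arms(df[df["arm"] == "armA"])

    def test_identical_arms_contrast_covers_zero(self):
        df = self._two_arm_dataset(16, 16, seed=8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", IdentifiabilityWarning)
            contrast = compare_arms(df, seed=0, **self._FIT_KW)
        assert contrast.delta_n_ci[0] <= 0 <= contrast.delta_n_ci[1]

    def test_halved_pool_detected(self):
        df = self._two_arm_dataset(16, 8, seed=9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", IdentifiabilityWarning)
            contrast = compare_arms(df, seed=0, **self._FIT_KW)
        assert contrast.delta_n < 0
        assert contrast.delta_n_ci[1] < 0  # CI excludes zero
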