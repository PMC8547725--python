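"""Effect decomposition: condition coding, predictions, RMSE fits."""

import numpy as np
import pandas as pd
import pytest

from flowparse.effects import (
    RETINAL_SPEED_TABLE,
    code_condition,
    coding_table,
    effect_correlation,
    fit_all_participants,
    fit_effects,
    predict_pse,
    predict_sd,
)

SPEEDS = (6.6, 8.0)
BACKDROPS = ("main", "blank_wall")


def _baselines(scale=1.0):
    bp = {(b, s): (2 / 3) * s * (1.0 if b == "main" else 1.02) for b in BACKDROPS for s in SPEEDS}
    bs = {k: 0.1 * v * scale for k, v in bp.items()}
    return bp, bs


def _fit_table(effects_acc, effects_prec, noise_sd=0.0, rng=None, subject="s01"):
    """Cell table generated exactly from the two linear models."""
    bp, bs = _baselines()
    rows = []
    for cond in ("main", "blank_wall", "moving_wall"):
        for prof in ("static", "same", "opposite"):
            for spd in SPEEDS:
                coding = code_condition(cond, prof)
                backdrop = "blank_wall" if cond == "blank_wall" else "main"
                if prof == "static":
                    pse, sd = bp[(backdrop, spd)], bs[(backdrop, spd)]
                else:
                    pse = predict_pse(bp, effects_acc, coding, spd)
                    sd = predict_sd(bs, effects_prec, coding, spd)
                if noise_sd > 0:
                    pse += rng.normal(0, noise_sd)
                    sd += rng.normal(0, noise_sd / 10)
                rows.append((subject, cond, prof, spd, pse, sd, 0.0, 110, True))
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "condition",
            "motion_profile",
            "standard_speed_mps",
            "pse",
            "sd",
            "log_likelihood",
            "n_trials",
            "converged",
        ],
    )


class TestConditionCoding:
    @pytest.mark.parametrize(
        "cond, prof, c_self, c_ind, c_prec",
        [
            ("main", "same", -1, 1, 1),
            ("main", "opposite", 1, -1, 1),
            ("main", "static", 0, 0, 0),
            ("blank_wall", "same", -1, 0, 1),
            ("blank_wall", "opposite", 1, 0, 1),
            ("blank_wall", "static", 0, 0, 0),
            ("moving_wall", "same", 0, -1, 0),
            ("moving_wall", "opposite", 0, 1, 0),
            ("moving_wall", "static", 0, 0, 0),
        ],
    )
    def test_full_coding_table(self, cond, prof, c_self, c_ind, c_prec):
        c = code_condition(cond, prof)
        assert c.cond_selfmotion == c_self
        assert c.cond_induced == c_ind
        assert c.cond_selfmotion_precision == c_prec

    def test_table_has_nine_unique_rows(self):
        table = coding_table()
        assert len(table) == 9
        assert not table.duplicated(["condition", "motion_profile"]).any()

    def test_retinal_velocity_lookup(self):
        assert code_condition("main", "same").retinal_velocity(6.6) == 27.6
        assert code_condition("main", "opposite").retinal_velocity(8.0) == 82.2
        # no visual self-motion: static retinal speeds, including moving wall
        assert code_condition("moving_wall", "opposite").retinal_velocity(6.6) == 46.6
        assert code_condition("blank_wall", "static").retinal_velocity(8.0) == 56.2

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            code_condition("outdoors", "same")
        with pytest.raises(ValueError):
            code_condition("main", "upward")


class TestPredictions:
    def test_zero_effects_return_baseline(self):
        bp, bs = _baselines()
        c = code_condition("main", "same")
        assert predict_pse(bp, (0, 0), c, 6.6) == bp[("main", 6.6)]
        assert predict_sd(bs, (0, 0), c, 6.6) == pytest.approx(
            bs[("main", 6.6)], abs=1e-12
        )

    def test_accuracy_substitution(self):
        bp = {("main", 6.6): 4.4}
        c = code_condition("main", "same")
        assert predict_pse(bp, (0.09, 0.11), c, 6.6) == pytest.approx(4.42)

    def test_moving_wall_only_induced_term(self):
        bp = {("main", 6.6): 4.4}
        c = code_condition("moving_wall", "opposite")
        assert predict_pse(bp, (0.5, 0.11), c, 6.6) == pytest.approx(4.51)

    def test_retinal_term_magnitude(self):
        bs = {("main", 6.6): 0.44}
        c = code_condition("main", "static")
        # static cell: only the retinal term moves the prediction
        assert predict_sd(bs, (0.5, 0.0016), c, 6.6) == pytest.approx(
            0.44 + 0.0016 * 46.6
        )

    def test_selfmotion_sd_term(self):
        bs = {("main", 6.6): 0.44}
        c = code_condition("main", "same")
        pred = predict_sd(bs, (0.031, 0.0), c, 6.6)
        assert pred == pytest.approx(0.44 + 0.031)

    def test_missing_baseline_raises(self):
        c = code_condition("blank_wall", "same")
        with pytest.raises(KeyError):
            predict_pse({("main", 6.6): 4.4}, (0, 0), c, 6.6)


class TestFitEffects:
    def test_noiseless_recovery_to_1e6(self):
        table = _fit_table((0.09, 0.11), (0.031, 0.0016))
        est = fit_effects(table, "s01")
        assert est.effect_selfmotion == pytest.approx(0.09, abs=1e-6)
        assert est.effect_induced == pytest.approx(0.11, abs=1e-6)
        assert est.effect_selfmotion_sd == pytest.approx(0.031, abs=1e-6)
        assert est.effect_retinal == pytest.approx(0.0016, abs=1e-6)
        assert est.rmse_accuracy < 1e-8 and est.rmse_precision < 1e-8

    def test_matches_closed_form_least_squares(self):
        """Numerical RMSE minimization agrees with the linear-algebra
        solution of the same (linear) model."""
        rng = np.random.default_rng(0)
        table = _fit_table((0.2, -0.05), (0.02, 0.001), noise_sd=0.15, rng=rng)
        est = fit_effects(table, "s01")

        bp, _ = _baselines()
        rows = []
        for r in table.itertuples():
            if r.motion_profile == "static":
                continue
            c = code_condition(r.condition, r.motion_profile)
            backdrop = "blank_wall" if r.condition == "blank_wall" else "main"
            rows.append(
                (
                    c.cond_selfmotion,
                    c.cond_induced,
                    r.pse - bp[(backdrop, r.standard_speed_mps)],
                )
            )
        A = np.array([(a, b) for a, b, _ in rows], dtype=float)
        resid = np.array([v for _, _, v in rows])
        ref, *_ = np.linalg.lstsq(A, resid, rcond=None)
        assert est.effect_selfmotion == pytest.approx(ref[0], abs=1e-5)
        assert est.effect_induced == pytest.approx(ref[1], abs=1e-5)

    def test_design_matrix_full_rank(self):
        rows_acc, rows_prec = [], []
        for cond in ("main", "blank_wall", "moving_wall"):
            for prof in ("same", "opposite"):
                for spd in SPEEDS:
                    c = code_condition(cond, prof)
                    rows_acc.append((c.cond_selfmotion, c.cond_induced))
                    rows_prec.append(
                        (c.cond_selfmotion_precision, c.retinal_velocity(spd))
                    )
        assert np.linalg.matrix_rank(np.array(rows_acc, dtype=float)) == 2
        assert np.linalg.matrix_rank(np.array(rows_prec, dtype=float)) == 2

    def test_observations_at_baseline_give_zero_effects(self):
        table = _fit_table((0.0, 0.0), (0.0, 0.0))
        est = fit_effects(table, "s01")
        assert est.effect_selfmotion == pytest.approx(0.0, abs=1e-7)
        assert est.effect_induced == pytest.approx(0.0, abs=1e-7)
        assert est.effect_selfmotion_sd == pytest.approx(0.0, abs=1e-7)
        assert est.effect_retinal == pytest.approx(0.0, abs=1e-8)

    def test_fitted_rmse_no_worse_than_zero_initialization(self):
        table = _fit_table(
            (0.1, 0.05), (0.02, 0.001), noise_sd=0.3, rng=np.random.default_rng(5)
        )
        est = fit_effects(table, "s01")
        # RMSE at the optimum <= RMSE of the (0, 0) model, using the same
        # observed-static baselines the fitter used
        bp = {
            (b if b != "moving_wall" else "main", r.standard_speed_mps): r.pse
            for r in table.itertuples()
            if r.motion_profile == "static"
            for b in [r.condition]
            if b != "moving_wall"
        }
        resid0 = []
        for r in table.itertuples():
            if r.motion_profile == "static":
                continue
            c = code_condition(r.condition, r.motion_profile)
            resid0.append(r.pse - predict_pse(bp, (0, 0), c, r.standard_speed_mps))
        rmse0 = float(np.sqrt(np.mean(np.square(resid0))))
        assert est.rmse_accuracy <= rmse0 + 1e-12

    def test_noisy_monte_carlo_recovery(self):
        rng = np.random.default_rng(8)
        frames = [
            _fit_table((0.09, 0.11), (0.031, 0.0016), noise_sd=0.2, rng=rng,
                       subject=f"s{i:02d}")
            for i in range(100)
        ]
        table = pd.concat(frames, ignore_index=True)
        est = fit_all_participants(table)
        for col, truth in (("effect_selfmotion", 0.09), ("effect_induced", 0.11)):
            se = est[col].std() / np.sqrt(len(est))
            assert abs(est[col].mean() - truth) < 3 * se

    def test_missing_cells_named(self):
        table = _fit_table((0.1, 0.1), (0.01, 0.001))
        table = table[table["condition"] != "blank_wall"]
        with pytest.raises(ValueError, match="blank_wall"):
            fit_effects(table, "s01")


class TestEffectCorrelation:
    def _estimates(self, x, y):
        return pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(len(x))],
                "effect_selfmotion": x,
                "effect_selfmotion_sd": y,
            }
        )

    def test_identical_vectors(self):
        x = [0.1, 0.2, 0.3, 0.15]
        r, _ = effect_correlation(self._estimates(x, x))
        assert r == pytest.approx(1.0)

    def test_anticorrelated_sign(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        r, _ = effect_correlation(self._estimates(x, -x + 0.5))
        assert r < 0

    def test_null_simulation_centers_at_zero(self):
        rng = np.random.default_rng(0)
        rs = []
        for _ in range(1000):
            x = rng.normal(0, 1, 10)
            y = rng.normal(0, 1, 10)
            r, _ = effect_correlation(self._estimates(x, y))
            rs.append(r)
        assert abs(np.mean(rs)) < 3 / np.sqrt(9 * 1000)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            effect_correlation(self._estimates([0.1, 0.1], [0.2, 0.3]))
        with pytest.raises(ValueError):
            effect_correlation(self._estimates([0.1] * 5, [0.2, 0.3, 0.1, 0.4, 0.2]))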