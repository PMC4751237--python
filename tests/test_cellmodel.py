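"""Cell model: R0, steady state, linearization, characteristic matrix."""

import json
import math

import numpy as np
import pytest

from quiescence.cellmodel import (
    CellModel,
    ExtinctionError,
    HypothesisError,
    ModelError,
    R0,
    ResponseFunction,
    SteadyState,
    UnboundedGrowthError,
    assess_stability,
    char_matrix_det,
    linearization_coeffs,
    load_model,
    model_from_dict,
    model_to_dict,
    solve_steady_state,
    trivial_state_matrix_det,
)
from quiescence.chareq import char_value, find_roots
from quiescence.fixtures import make_fixture

from conftest import random_valid_model


class TestResponseFunction:
    def test_hill_value_and_derivative(self):
        f = ResponseFunction("hill_increasing", (2.0, 3.0, 0.4))
        E = 0.7
        expected = 2.0 * E**3 / (E**3 + 0.4**3)
        assert f.value(E) == pytest.approx(expected, rel=1e-12)
        fd = (f.value(E + 1e-7) - f.value(E - 1e-7)) / 2e-7
        assert f.derivative(E) == pytest.approx(fd, rel=1e-6)

    def test_hill_stable_at_extreme_exponent(self):
        f = ResponseFunction("hill_increasing", (1.0, 1000.0, 0.5))
        assert f.value(0.5) == pytest.approx(0.5)
        assert f.value(0.2) == 0.0
        assert math.isfinite(f.derivative(0.2))
        assert f.derivative(0.5) > 0

    def test_linear_clamp(self):
        f = ResponseFunction("linear_clamped", (0.2, -0.5))
        assert f.value(0.1) == pytest.approx(0.15)
        assert f.value(0.9) == 0.0
        assert f.derivative(0.9) == 0.0

    def test_custom_without_derivative_warns(self):
        with pytest.warns(UserWarning, match="central differences"):
            f = ResponseFunction("custom", func=lambda E: E**2)
        assert f.derivative(0.3) == pytest.approx(0.6, abs=1e-6)

    def test_unknown_family_rejected(self):
        with pytest.raises(ModelError):
            ResponseFunction("sigmoid", (1.0,))


class TestR0:
    def test_no_death_gives_two(self):
        m = CellModel(
            0.0, 0.5,
            ResponseFunction("constant", (0.3,)),
            ResponseFunction("constant", (1.0,)),
        )
        assert R0(0.7, m) == pytest.approx(2.0)

    def test_unit_commitment_probability_gives_survival(self):
        # beta1 == 1 collapses R0 to 2 e^{-mu} for any G
        m = CellModel(
            0.3, 0.5,
            ResponseFunction("constant", (1.0,)),
            ResponseFunction("hill_increasing", (1.0, 2.0, 0.5)),
            validate=False,
        )
        assert R0(0.6, m) == pytest.approx(2 * math.exp(-0.3))

    def test_steady_state_level_of_g(self):
        # G(E) = (1 - 2 beta1 e^{-mu}) mu / (2 e^{-mu} - 1)  <=>  R0(E) = 1
        mu, b1 = 0.4, 0.3
        em = math.exp(-mu)
        g = (1 - 2 * b1 * em) * mu / (2 * em - 1)
        m = CellModel(
            mu, 0.5,
            ResponseFunction("constant", (b1,)),
            ResponseFunction("constant", (g,)),
        )
        assert R0(0.5, m) == pytest.approx(1.0, abs=1e-12)

    def test_exceeds_direct_renewal_share(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            m = random_valid_model(rng)
            E = rng.uniform(0.05, 0.95)
            assert R0(E, m) > m.survival * m.beta1.value(E)


class FrozenFig4:
    """Closed-form evaluation of the reference steady state, written out
    from the defining formulas independently of the solver."""

    mu = 0.5
    em = math.exp(-0.5)
    theta = 0.8
    Ebar = 0.5
    b1 = 0.5
    a3 = 2 * em * b1  # = e^{-1/2}
    g = (1 - a3) * mu / (2 * em - 1)
    l = (3 * em - 2) / (2 * em - 1)
    K = (1 / Ebar - 1) / ((1 - a3) * (1 - l * theta))
    pbar = (1 / Ebar - 1) / (1 - l * theta) * mu / (2 * em - 1)
    Qbar = (1 / Ebar - 1) / (1 - l * theta)
    # Hill G with half = Ebar: G'(Ebar) = vmax n / (4 half) = n g / (2 Ebar)
    A = (2.0 * g / (2 * 0.5)) * Ebar * (1 - Ebar)  # n = 2, beta1' = 0


class TestSteadyState:
    def test_reference_fixture_values(self, fig4_model, fig4_ss):
        f = FrozenFig4
        assert fig4_ss.Ebar == pytest.approx(0.5, abs=1e-9)
        assert fig4_ss.K == pytest.approx(f.K, rel=1e-9)
        assert fig4_ss.pbar == pytest.approx(f.pbar, rel=1e-9)
        assert fig4_ss.Qbar == pytest.approx(f.Qbar, rel=1e-9)
        assert fig4_ss.l == pytest.approx(f.l, rel=1e-12)
        assert fig4_ss.A == pytest.approx(f.A, rel=1e-9)

    def test_population_ratio_invariant(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            m = random_valid_model(rng)
            ss = solve_steady_state(m)
            mu = m.death_rate
            assert ss.pbar / ss.Qbar == pytest.approx(
                mu / (2 * math.exp(-mu) - 1), rel=1e-9
            )
            assert ss.l < 1
            assert 0 < ss.Ebar < 1
            assert ss.A > 0
            assert abs(R0(ss.Ebar, m) - 1) < 1e-9

    def test_extinction_regime_error(self):
        with pytest.raises(ExtinctionError):
            solve_steady_state(make_fixture("extinction"))

    def test_unbounded_growth_regime_error(self):
        with pytest.raises(UnboundedGrowthError):
            solve_steady_state(make_fixture("blowup"))

    def test_hypothesis_violation_error(self):
        # R0(0) < 1 < R0(1) holds, but G decreases so the monotonicity
        # hypothesis fails near E = 0
        m = CellModel(
            0.3, 0.5,
            ResponseFunction("hill_increasing", (0.7, 4.0, 0.5)),
            ResponseFunction("linear_clamped", (0.4, -0.3)),
        )
        assert R0(0.0, m) < 1 < R0(1.0, m)
        with pytest.raises(HypothesisError):
            solve_steady_state(m)

    def test_uniqueness_single_sign_change(self):
        """Under the hypothesis, R0 - 1 changes sign exactly once on a
        fine grid for random valid models."""
        rng = np.random.default_rng(12)
        for _ in range(100):
            m = random_valid_model(rng)
            vals = np.array([R0(E, m) - 1 for E in np.linspace(0, 1, 400)])
            assert (np.diff(np.sign(vals)) != 0).sum() == 1

    def test_transcritical_determinant_identity(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            m = random_valid_model(rng)
            E = rng.uniform(0.05, 0.95)
            det = trivial_state_matrix_det(E, m)
            mu, g = m.death_rate, m.G.value(E)
            assert det == pytest.approx((mu + g) * (R0(E, m) - 1), rel=1e-10, abs=1e-12)
            ss = solve_steady_state(m)
            assert abs(trivial_state_matrix_det(ss.Ebar, m)) < 1e-9


class TestLinearization:
    def test_transcritical_identity_on_random_models(self):
        """a1 + a2 = (1 - 2 e^{-mu}) A(Ebar), and 0 < a3 < 1."""
        rng = np.random.default_rng(14)
        for _ in range(100):
            m = random_valid_model(rng)
            ss = solve_steady_state(m)
            c = linearization_coeffs(m, ss)
            resid = c.alpha1 + c.alpha2 - (1 - 2 * math.exp(-m.death_rate)) * ss.A
            assert abs(resid) < 1e-10
            assert 0 < c.alpha3 < 1
            assert c.alpha1 + c.alpha2 < 0

    def test_neutral_coefficient_independent_of_theta(self, fig4_model, fig4_ss):
        a3s = set()
        for th in (0.0, 0.5, 1.0):
            m = CellModel(
                fig4_model.death_rate, th, fig4_model.beta1, fig4_model.G
            )
            a3s.add(linearization_coeffs(m, fig4_ss).alpha3)
        assert len(a3s) == 1

    def test_flat_response_sits_on_transcritical_line(self, fig4_model, fig4_ss):
        flat = SteadyState(
            Ebar=fig4_ss.Ebar, pbar=fig4_ss.pbar, Qbar=fig4_ss.Qbar,
            K=fig4_ss.K, l=fig4_ss.l, A=0.0,
        )
        c = linearization_coeffs(fig4_model, flat)
        assert c.alpha1 + c.alpha2 == pytest.approx(0.0, abs=1e-12)


class TestCharMatrix:
    def test_scalar_roots_are_matrix_roots(self, fig4_model, fig4_ss):
        c = linearization_coeffs(fig4_model, fig4_ss)
        roots = find_roots(c, re_min=-2.0)
        assert roots
        for r in roots:
            assert abs(char_matrix_det(r.as_complex(), fig4_model, fig4_ss)) < 1e-8

    def test_removable_singularity(self, fig4_model, fig4_ss):
        v = char_matrix_det(-fig4_model.death_rate, fig4_model, fig4_ss)
        assert np.isfinite(v.real) and np.isfinite(v.imag)
        near = char_matrix_det(-fig4_model.death_rate + 1e-9, fig4_model, fig4_ss)
        assert abs(v - near) < 1e-6

    def test_nonzero_off_root_set(self, fig4_model, fig4_ss):
        c = linearization_coeffs(fig4_model, fig4_ss)
        rng = np.random.default_rng(15)
        for _ in range(50):
            lam = complex(*rng.uniform(-3, 3, 2))
            if abs(char_value(lam, c)) > 1e-3:
                assert abs(char_matrix_det(lam, fig4_model, fig4_ss)) > 1e-6

    def test_zero_sets_coincide_in_disk(self):
        """Dual-route check on random models: all scalar roots in the disk
        |lambda| <= 10 are matrix-determinant zeros, and an independent
        Newton search on det M finds no zero away from them."""
        rng = np.random.default_rng(16)
        for _ in range(10):
            m = random_valid_model(rng)
            ss = solve_steady_state(m)
            c = linearization_coeffs(m, ss)
            scalar = [
                r.as_complex()
                for r in find_roots(c, re_min=-10.0, im_max=10.0)
                if abs(r.as_complex()) <= 10.0
            ]
            for z in scalar:
                assert abs(char_matrix_det(z, m, ss)) < 1e-8
            # independent root search on det M (secant-style Newton)
            seeds = [
                complex(x, y)
                for x in np.arange(-10, 10.5, 1.0)
                for y in np.arange(0, 10.5, 1.0)
            ]
            found = []
            h = 1e-7
            for z in seeds:
                for _ in range(60):
                    f = char_matrix_det(z, m, ss)
                    df = (char_matrix_det(z + h, m, ss) - char_matrix_det(z - h, m, ss)) / (2 * h)
                    if df == 0:
                        break
                    step = f / df
                    if abs(step) > 1.5:
                        step *= 1.5 / abs(step)
                    z = z - step
                    if abs(step) < 1e-13:
                        break
                if abs(char_matrix_det(z, m, ss)) < 1e-10 and abs(z) <= 10.0:
                    found.append(z)
            for z in found:
                dist = min(
                    min(abs(z - s) for s in scalar),
                    min(abs(z.conjugate() - s) for s in scalar),
                )
                assert dist < 1e-6, (z, scalar)


class TestAssessStability:
    def test_reference_settings_stable(self):
        verdict, c, ss = assess_stability(make_fixture("fig4", theta=0.8))
        assert verdict.stable
        assert c.alpha3 == pytest.approx(math.exp(-0.5))

    def test_high_consumption_weight_stable_regardless_of_steepness(self):
        v, _, _ = assess_stability(make_fixture("steep", theta=0.8))
        assert v.stable
        v10, _, _ = assess_stability(make_fixture("steep", hill_n=1000.0, theta=0.8))
        assert v10.stable

    def test_steep_low_weight_unstable_with_pair(self):
        from quiescence.chareq import count_unstable_roots

        v, c, _ = assess_stability(make_fixture("steep", theta=0.5))
        assert not v.stable
        assert count_unstable_roots(c).n_unstable >= 2


class TestConfigIO:
    def test_round_trip_toml_and_json(self, tmp_path, fig4_model):
        d = model_to_dict(fig4_model)
        j = tmp_path / "m.json"
        j.write_text(json.dumps(d))
        m2 = load_model(j)
        assert model_to_dict(m2) == d

        t = tmp_path / "m.toml"
        t.write_text(
            "death_rate = {death_rate}\ntheta = {theta}\n"
            "[beta1]\nfamily = \"{bf}\"\nparams = {bp}\n"
            "[G]\nfamily = \"{gf}\"\nparams = {gp}\n".format(
                death_rate=d["death_rate"], theta=d["theta"],
                bf=d["beta1"]["family"], bp=d["beta1"]["params"],
                gf=d["G"]["family"], gp=d["G"]["params"],
            )
        )
        m3 = load_model(t)
        assert model_to_dict(m3) == d

    def test_unknown_keys_rejected(self):
        with pytest.raises(ModelError, match="unknown"):
            model_from_dict(
                {
                    "death_rate": 0.5, "theta": 0.5, "tau": 2.0,
                    "beta1": {"family": "constant", "params": [0.5]},
                    "G": {"family": "constant", "params": [1.0]},
                }
            )
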