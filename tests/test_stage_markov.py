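"""Disease-stage chain: construction, fundamental matrix, solver, MC oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adcostsim.stage_markov import (
    SCENARIO_IDS,
    StageTransitionModel,
    build_baseline_model,
    build_scenario_model,
    expected_stage_years,
    fundamental_matrix,
    mc_stage_walk,
    scenario_incidence_multiplier,
    solve_prolongation,
)

# Frozen oracle values: dense linear solve of (I - Q) n = I for the baseline
# chain, cross-checked below against the Neumann series and Monte-Carlo walkers.
BASELINE_YEARS = np.array([4.921354, 1.603228, 0.801316])
BASELINE_MIX = np.array([0.671775, 0.218844, 0.109381])


class TestModelConstruction:
    def test_baseline_matches_published_probabilities(self):
        m = build_baseline_model()
        assert m.q[0, 0] == 0.774
        assert m.q[1, 0] == 0.070 and m.q[1, 1] == 0.501 and m.q[1, 2] == 0.214
        assert m.q[2, 1] == 0.028 and m.q[2, 0] == 0.0
        assert tuple(m.death) == (0.055, 0.215, 0.480)
        np.testing.assert_allclose(m.q.sum(axis=1) + m.death, 1.0, atol=1e-15)

    @pytest.mark.parametrize(
        "name, row, qrow, death",
        [
            ("mild+1", 0, (0.814, 0.121, 0.010), 0.055),
            ("mild+2", 0, (0.844, 0.092, 0.009), 0.055),
            ("moderate+1", 1, (0.050, 0.700, 0.040), 0.210),
            # death probabilities of the Moderate scenarios and the Severe stay
            # are the residuals completing the unit row sum
            ("moderate+2", 1, (0.040, 0.770, 0.004), 0.186),
            ("severe+1", 2, (0.000, 0.028, 0.772), 0.200),
        ],
    )
    def test_scenario_rows(self, name, row, qrow, death):
        base = build_baseline_model()
        m = build_scenario_model(name)
        np.testing.assert_allclose(m.q[row], qrow, atol=1e-12)
        assert m.death[row] == pytest.approx(death, abs=1e-12)
        # unnamed rows stay at baseline
        for i in range(3):
            if i != row:
                np.testing.assert_array_equal(m.q[i], base.q[i])
                assert m.death[i] == base.death[i]

    def test_unknown_scenario_rejected_with_valid_ids(self):
        with pytest.raises(ValueError, match="mild\\+1"):
            build_scenario_model("nonsense")
        with pytest.raises(ValueError):
            scenario_incidence_multiplier("nonsense")

    def test_mci_scenarios_carry_baseline_matrix_and_multiplier(self):
        base = build_baseline_model()
        for name, mult in [("mci-10", 0.9), ("mci-30", 0.7), ("mci-50", 0.5)]:
            m = build_scenario_model(name)
            np.testing.assert_array_equal(m.q, base.q)
            assert scenario_incidence_multiplier(name) == mult
        assert scenario_incidence_multiplier("reference") == 1.0
        assert len(SCENARIO_IDS) == 9

    def test_invalid_rows_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            StageTransitionModel(q=np.eye(3) * 0.5, death=np.array([0.1, 0.1, 0.1]))
        bad = np.array([[0.7, 0.2, 0.045], [0.07, 0.501, 0.214], [0.05, 0.028, 0.442]])
        with pytest.raises(ValueError, match="Severe"):
            StageTransitionModel(q=bad, death=np.array([0.055, 0.215, 0.480]))

    def test_dict_round_trip(self):
        m = build_scenario_model("moderate+2")
        again = StageTransitionModel.from_dict(m.to_dict())
        np.testing.assert_array_equal(again.q, m.q)
        np.testing.assert_array_equal(again.death, m.death)
        assert again.name == "moderate+2"


class TestFundamentalMatrix:
    def test_baseline_sojourns_and_limit_mix(self, baseline):
        fs = fundamental_matrix(baseline)
        np.testing.assert_allclose(fs.years_from_mild, BASELINE_YEARS, atol=1e-6)
        np.testing.assert_allclose(fs.limit_mix, BASELINE_MIX, atol=1e-6)
        assert fs.limit_mix.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(fs.n @ (np.eye(3) - baseline.q), np.eye(3), atol=1e-9)

    def test_immediate_absorption_gives_identity(self):
        m = StageTransitionModel(q=np.zeros((3, 3)), death=np.ones(3))
        fs = fundamental_matrix(m)
        np.testing.assert_array_equal(fs.n, np.eye(3))
        np.testing.assert_array_equal(fs.years_from_mild, [1.0, 0.0, 0.0])

    def test_matches_truncated_neumann_series(self, baseline):
        total = np.eye(3)
        term = np.eye(3)
        for _ in range(10_000):
            term = term @ baseline.q
            total += term
        np.testing.assert_allclose(fundamental_matrix(baseline).n, total, atol=1e-6)

    def test_singular_chain_rejected(self):
        q = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        with pytest.raises(ValueError):
            fundamental_matrix(StageTransitionModel(q=q, death=np.zeros(3)))

    @pytest.mark.parametrize(
        "name, stage, gain",
        [
            ("mild+1", 0, 1.012),
            ("mild+2", 0, 2.086),
            ("moderate+1", 1, 1.070),
            ("moderate+2", 1, 1.879),
            ("severe+1", 2, 1.046),
        ],
    )
    def test_scenario_sojourn_gains(self, name, stage, gain):
        base_years = expected_stage_years(build_baseline_model())
        scen_years = expected_stage_years(build_scenario_model(name))
        measured = scen_years[stage] - base_years[stage]
        assert measured == pytest.approx(gain, abs=1e-3)
        # each published matrix delivers its advertised whole-year prolongation
        assert round(measured) == round(gain)

    def test_death_entry_rejected(self, baseline):
        with pytest.raises(ValueError):
            expected_stage_years(baseline, "Death")


class TestProlongationSolver:
    def test_one_year_mild_reproduces_published_scenario(self, baseline):
        solved = solve_prolongation(baseline, "Mild", 1.0)
        assert solved.q[0, 0] == pytest.approx(0.8136, abs=5e-5)
        assert round(100 * solved.q[0, 0], 1) == 81.4
        assert solved.q[0, 1] == pytest.approx(0.1214, abs=5e-5)
        assert solved.q[0, 2] == pytest.approx(0.0100, abs=5e-5)
        assert solved.death[0] == baseline.death[0]  # death held fixed

    def test_zero_delta_returns_model_unchanged(self, baseline):
        assert solve_prolongation(baseline, "Mild", 0.0) is baseline

    def test_hits_target_sojourn_exactly(self, baseline):
        base = expected_stage_years(baseline)
        for stage, delta in [(0, 0.5), (1, 1.2), (2, 1.0)]:
            solved = solve_prolongation(baseline, stage, delta)
            got = expected_stage_years(solved)[stage]
            assert got == pytest.approx(base[stage] + delta, abs=1e-9)

    def test_monotone_in_delta(self, baseline):
        stays = [
            solve_prolongation(baseline, "Mild", d).q[0, 0] for d in (0.25, 0.5, 1.0, 2.0)
        ]
        assert all(b > a for a, b in zip(stays, stays[1:]))

    def test_severe_policy_lowers_death(self, baseline):
        solved = solve_prolongation(baseline, "Severe", 1.0)
        assert solved.death[2] < baseline.death[2]
        assert solved.q[2, 1] == baseline.q[2, 1]  # improvement untouched
        got = expected_stage_years(solved)[2]
        assert got == pytest.approx(expected_stage_years(baseline)[2] + 1.0, abs=1e-9)

    def test_unreachable_delta_reports_attainable_maximum(self, baseline):
        with pytest.raises(ValueError, match="attainable maximum"):
            solve_prolongation(baseline, "Mild", 50.0)
        with pytest.raises(ValueError, match="attainable maximum"):
            solve_prolongation(baseline, "Severe", 100.0)


class TestMonteCarloOracle:
    def test_agrees_with_fundamental_matrix(self, baseline):
        walkers = 200_000
        fs = fundamental_matrix(baseline)
        # closed-form occupation-time variance of the absorbing chain
        ndg = np.diag(np.diag(fs.n))
        var = (fs.n @ (2 * ndg - np.eye(3)) - fs.n * fs.n)[0]
        emp = mc_stage_walk(baseline, walkers, seed=20240917)
        z = np.abs(emp - fs.years_from_mild) / np.sqrt(var / walkers)
        assert (z < 3).all(), f"z-scores {z}"

    def test_immediate_absorption_exact(self):
        m = StageTransitionModel(q=np.zeros((3, 3)), death=np.ones(3))
        np.testing.assert_array_equal(mc_stage_walk(m, 50, seed=1), [1.0, 0.0, 0.0])

    def test_deterministic_given_seed(self, baseline):
        a = mc_stage_walk(baseline, 10, seed=5)
        b = mc_stage_walk(baseline, 10, seed=5)
        np.testing.assert_array_equal(a, b)


@st.composite
def transition_models(draw):
    rows = []
    deaths = []
    for i in range(3):
        raw = [draw(st.floats(0.01, 1.0)) for _ in range(4)]
        if i == 2:
            raw[0] = 0.0
        total = sum(raw)
        # leave some probability of death so the chain is absorbing
        rows.append([r / total * 0.95 for r in raw[:3]])
        deaths.append(1.0 - sum(rows[-1]))
    return StageTransitionModel(q=np.array(rows), death=np.array(deaths))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(transition_models())
def test_solver_and_algebra_preserve_row_stochasticity(model):
    """Any valid chain stays row-stochastic through the solver, and its
    fundamental matrix inverts (I - Q) to machine precision."""
    fs = fundamental_matrix(model)
    np.testing.assert_allclose(fs.n @ (np.eye(3) - model.q), np.eye(3), atol=1e-8)
    assert fs.limit_mix.sum() == pytest.approx(1.0, abs=1e-12)
    try:
        solved = solve_prolongation(model, "Mild", 0.3)
    except ValueError:
        return  # unreachable prolongation is a legitimate outcome
    rows = solved.q.sum(axis=1) + solved.death
    np.testing.assert_allclose(rows, 1.0, atol=1e-12)
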