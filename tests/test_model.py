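"""Model core: GMA structure, S-system extraction, steady states, dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import fsolve

from phenospace import (
    CLOCK_PARAMETERS,
    PowerLawTerm,
    Signature,
    build_clock_model,
    eigenvalues_at,
    extract_ssystem,
    simulate,
    solve_steady_state,
)
from phenospace.design_space import _dominance_constraints
from phenospace.model import InvalidModelError, _aux_values
from scipy.optimize import linprog

SIG7 = "11 11 21 11 21 11"
SIG1 = "11 11 11 11 11 11"


def sig(clock, text):
    for cand in clock.candidate_signatures():
        if str(cand) == text:
            return cand
    raise AssertionError(f"signature {text} not enumerable")


def max_margin_point(clock, space, num):
    """Interior point of a region maximizing the smallest dominance margin
    (log10 of dominant/subdominant term ratio) -- where the S-system
    approximation of the full GMA system is most accurate."""
    reg = space.regions[num]
    forms = _dominance_constraints(clock, reg.signature, reg.ssystem, space.slice)
    free = space.slice.free_parameters
    # maximize t subject to f_i(x) >= t within the box
    A, b = [], []
    for f in forms:
        A.append([-f.coeffs.get(p, 0.0) for p in free] + [1.0])
        b.append(f.const)
    res = linprog(
        c=[0.0, 0.0, -1.0],
        A_ub=A,
        b_ub=b,
        bounds=[space.slice.bounds(p) for p in free] + [(0, None)],
        method="highs",
    )
    assert res.success
    return dict(zip(free, res.x[:2]))


class TestStructure:
    def test_clock_layout(self, clock):
        kinds = [eq.kind for eq in clock.equations]
        assert kinds == ["differential"] * 4 + ["algebraic"] * 2
        assert clock.dependent_variables == ("mP", "P", "mN", "N")
        assert clock.auxiliary_variables == ("DP", "DN")
        assert len(list(clock.candidate_signatures())) == 16

    @pytest.mark.parametrize("n,p", [(0.5, 2), (2, 0), (-1, 2)])
    def test_invalid_kinetic_orders(self, n, p):
        with pytest.raises(InvalidModelError):
            build_clock_model(n, p)

    def test_unit_orders_change_exponents_only(self):
        unit = build_clock_model(1, 1)
        dp = unit.equation_for("DP")
        assert dp.positive_terms[1].exponents == {"N": 1.0, "K_N": -1.0}

    def test_out_of_range_signature_raises(self, clock):
        bad = Signature(pairs=((3, 1),) + ((1, 1),) * 5, label=0)
        with pytest.raises(IndexError):
            extract_ssystem(clock, bad)


class TestSSystemExtraction:
    def test_signature7_reproduces_reduced_equations(self, clock):
        """The oscillatory phenotype's S-system: repression of mP synthesis by
        (N/K_N)^-n, activation of mN synthesis by (P/K_P)^p, linear turnover."""
        ss = extract_ssystem(clock, sig(clock, SIG7))
        n = clock.kinetic_orders["n"]
        p = clock.kinetic_orders["p"]
        expected_pos = [
            {"alpha_mPmax": 1, "N": -n, "K_N": n},
            {"alpha_P": 1, "mP": 1},
            {"alpha_mNmax": 1, "P": p, "K_P": -p},
            {"alpha_N": 1, "mN": 1},
        ]
        expected_neg = [
            {"beta_mP": 1, "mP": 1},
            {"beta_P": 1, "P": 1},
            {"beta_mN": 1, "mN": 1},
            {"beta_N": 1, "N": 1},
        ]
        for term, exp in zip(ss.positive, expected_pos):
            assert term.coefficient == 1.0
            assert term.exponents == {k: float(v) for k, v in exp.items()}
        for term, exp in zip(ss.negative, expected_neg):
            assert term.exponents == {k: float(v) for k, v in exp.items()}

    def test_signature1_fully_derepressed(self, clock):
        """With both auxiliaries dominated by the constant term, mP synthesis is
        fully derepressed and mN synthesis basal."""
        ss = extract_ssystem(clock, sig(clock, SIG1))
        assert ss.positive[0].exponents == {"alpha_mPmax": 1.0}
        assert ss.positive[2].exponents == {"alpha_mNmin": 1.0}


class TestSteadyState:
    def test_published_operating_point(self, clock):
        """Normalized steady state of the oscillatory phenotype at the scaled
        parameter table: mP = 100.0, P = 1.0, mN = 3.16, N = 3.16."""
        ss = solve_steady_state(extract_ssystem(clock, sig(clock, SIG7)), CLOCK_PARAMETERS)
        assert ss["mP"] == pytest.approx(100.0, rel=5e-3)
        assert ss["P"] == pytest.approx(1.0, rel=5e-3)
        assert ss["mN"] == pytest.approx(3.16, rel=5e-3)
        assert ss["N"] == pytest.approx(3.16, rel=5e-3)

    def test_unit_parameters_finite(self, clock):
        params = {k: 1.0 for k in CLOCK_PARAMETERS}
        for text in (SIG1, SIG7):
            ss = solve_steady_state(extract_ssystem(clock, sig(clock, text)), params)
            assert all(np.isfinite(v) for v in ss.log_values.values())

    def test_residuals_all_phenotypes(self, clock, clock_space):
        for num in clock_space.numbers:
            reg = clock_space.regions[num]
            env = {**reg.steady_state.values,
                   **clock_space.slice.parameter_values(reg.centroid)}
            for tp, tn in zip(reg.ssystem.positive, reg.ssystem.negative):
                resid = abs(math.log10(tp.evaluate(env)) - math.log10(tn.evaluate(env)))
                assert resid < 1e-10

    def test_matches_full_system_integration(self, clock, clock_space):
        """S-system steady state of a monotone phenotype agrees with the
        long-time limit of the full GMA system started inside its region
        (at a deep-interior point, where dominance margins are largest)."""
        from phenospace import solve_steady_state as _solve

        point = max_margin_point(clock, clock_space, 11)
        reg = clock_space.regions[11]
        params = clock_space.slice.parameter_values(point)
        state = _solve(reg.ssystem, params)
        init = {k: v * 2.0 for k, v in state.values.items()}
        traj = simulate(clock, params, init, horizon=60.0)
        final = traj.iloc[-1]
        for var in clock.dependent_variables:
            assert final[var] == pytest.approx(state[var], rel=1e-2)


class TestEigenvalues:
    def test_only_oscillatory_phenotype_has_complex_pair(self, clock_space):
        for num in clock_space.numbers:
            eig = clock_space.regions[num].eigen
            if num == 7:
                assert eig.has_complex_pair
                assert eig.max_real_part == pytest.approx(0.0, abs=1e-9)
            else:
                assert not eig.has_complex_pair
                assert eig.max_real_part < -1e-6

    def test_consistent_with_full_system_jacobian(self, clock, clock_space):
        """Finite-difference Jacobian of the full GMA system at its own fixed
        point shows the same oscillatory signature as the dominance reduction."""
        reg = clock_space.regions[7]
        params = clock_space.slice.parameter_values(reg.centroid)
        names = list(clock.dependent_variables)

        def rhs(y):
            env = {**params, **dict(zip(names, y))}
            env.update(_aux_values(clock, env))
            out = []
            for v in names:
                eq = clock.equation_for(v)
                out.append(sum(t.evaluate(env) for t in eq.positive_terms)
                           - sum(t.evaluate(env) for t in eq.negative_terms))
            return out

        x0 = fsolve(rhs, [reg.steady_state[v] for v in names], xtol=1e-13)
        h = 1e-6
        J = np.zeros((4, 4))
        for j in range(4):
            dx = np.array(x0, dtype=float)
            dx[j] += h * x0[j]
            J[:, j] = (np.array(rhs(dx)) - np.array(rhs(x0))) / (h * x0[j])
        ev_full = np.linalg.eigvals(J)
        assert np.any(np.abs(ev_full.imag) > 0.1)  # oscillatory pair
        im_full = np.max(np.abs(ev_full.imag))
        im_red = max(abs(e.imag) for e in reg.eigen.eigenvalues)
        assert im_full == pytest.approx(im_red, rel=0.3)
        # full system is damped: the dominance reduction sits at the margin
        assert ev_full.real.max() < 0.05


class TestStabilityThreshold:
    @pytest.mark.parametrize("loop_gain", [3.0, 3.5, 4.0, 4.5, 6.0])
    def test_routh_hurwitz_closed_form(self, loop_gain):
        """With equal relaxation rates beta the four-stage loop satisfies
        (lambda/beta + 1)^4 = -n*p, so the complex pair crosses the axis at
        loop cooperativity n*p = 4."""
        n = p = math.sqrt(loop_gain)
        system = build_clock_model(n, p)
        ss7 = extract_ssystem(system, sig(system, SIG7))
        state = solve_steady_state(ss7, CLOCK_PARAMETERS)
        eig = eigenvalues_at(ss7, CLOCK_PARAMETERS, state)
        beta = 1.0
        predicted = beta * (loop_gain**0.25 / math.sqrt(2.0) - 1.0)
        assert eig.max_real_part == pytest.approx(predicted, abs=1e-8)
        if loop_gain < 4.0:
            assert eig.max_real_part < 0
        elif loop_gain > 4.0:
            assert eig.max_real_part > 0


class TestSimulation:
    def test_damped_oscillation_and_period(self, clock):
        """The published simulation: damped oscillation of P with successive
        peaks decreasing, period set by the dominant eigenvalue pair."""
        init = {"mP": 100.0, "P": 1.0, "mN": 3.16, "N": 1.58}
        traj = simulate(clock, CLOCK_PARAMETERS, init, horizon=75.0,
                        time_scale=1.0 / 3.0, n_points=6000)
        P = traj["P"].to_numpy()
        t = traj["time"].to_numpy()
        peaks = [i for i in range(1, len(P) - 1) if P[i] > P[i - 1] and P[i] > P[i + 1]]
        assert len(peaks) >= 3
        amplitudes = P[peaks]
        assert np.all(np.diff(amplitudes) < 0)  # damped
        period = float(np.mean(np.diff(t[peaks])))
        ss7 = extract_ssystem(clock, sig(clock, SIG7))
        state = solve_steady_state(ss7, CLOCK_PARAMETERS)
        eig = eigenvalues_at(ss7, CLOCK_PARAMETERS, state)
        omega = max(abs(e.imag) for e in eig.eigenvalues)
        # the dominance eigenvalue predicts the full-system period to within
        # the accuracy of the approximation (~20% at this operating point)
        assert period == pytest.approx((2 * math.pi / omega) / 3.0, rel=0.2)

    def test_monotone_relaxation_in_region1(self, clock, clock_space):
        reg = clock_space.regions[1]
        params = clock_space.slice.parameter_values(reg.centroid)
        traj = simulate(clock, params, {"mP": 1.0, "P": 1.0, "mN": 1.0, "N": 1.0},
                        horizon=40.0)
        P = traj["P"].to_numpy()
        dP = np.diff(P)
        settle = len(dP) // 4
        tail = dP[settle:]
        signs = np.sign(tail[np.abs(tail) > 1e-6 * np.abs(P).max()])
        assert len(set(signs.tolist())) <= 1  # no oscillation after transient

    @pytest.mark.parametrize("num", [1, 6, 7, 11, 16])
    def test_dominance_consistency(self, clock, clock_space, num):
        """Starting the full system at the S-system steady state at a
        well-conditioned interior point of its own region, trajectories stay
        within 5% of that state for ten relaxation times.  For the oscillatory
        phenotype the dominance margins are structurally bounded (both
        regulators operate in their regulatable range), and its published
        centroid operating point is the accurate one."""
        from phenospace import solve_steady_state as _solve

        point = clock_space.regions[7].centroid if num == 7 else max_margin_point(
            clock, clock_space, num)
        reg = clock_space.regions[num]
        params = clock_space.slice.parameter_values(point)
        state = _solve(reg.ssystem, params)
        traj = simulate(clock, params, dict(state.values), horizon=10.0)
        for var in clock.dependent_variables:
            rel = np.abs(traj[var] / state[var] - 1.0)
            assert rel.max() < 0.05

    def test_nonpositive_init_rejected(self, clock):
        with pytest.raises(ValueError):
            simulate(clock, CLOCK_PARAMETERS, {"mP": 0.0, "P": 1, "mN": 1, "N": 1}, 1.0)


class TestPowerLawAlgebra:
    @given(
        coeff=st.floats(0.01, 100),
        g=st.floats(-3, 3),
        sub_coeff=st.floats(0.01, 100),
        sub_e=st.floats(-2, 2),
        x=st.floats(0.1, 10),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_substitution_preserves_value(self, coeff, g, sub_coeff, sub_e, x):
        """Replacing a variable by a power-law term is exact power-law closure."""
        term = PowerLawTerm(coeff, {"A": g, "x": 1.5})
        repl = PowerLawTerm(sub_coeff, {"x": sub_e})
        merged = term.substitute("A", repl)
        a_val = repl.evaluate({"x": x})
        direct = term.evaluate({"A": a_val, "x": x})
        assert merged.evaluate({"x": x}) == pytest.approx(direct, rel=1e-10)
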