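"""Stochastic gate-opening simulator against exact and closed-form oracles."""

import math

import numpy as np
import pytest

from gatekmc import (
    CD_ADA,
    CD_CA,
    GateGeometry,
    HostGuestPair,
    MixtureSpec,
    build_gate,
    master_equation_oracle,
    opening_probability,
    simulate_gate,
    sweep_koff_fixed_Keq,
)
from gatekmc.gate import DiffusionModel
from gatekmc.kmc import ConfigurationError, simulate_ensemble

from conftest import pure_unbinding_geometry


class TestSingleGate:
    def test_empty_gate_opens_immediately(self):
        geo = GateGeometry(n_units=0)
        gate = build_gate(MixtureSpec(p_fast=1.0), geometry=geo, seed=0)
        fp = simulate_gate(gate, geometry=geo)
        assert fp.opened and fp.time == 0.0

    def test_exponential_first_passage_mean(self, single_bond_pure_unbinding):
        # one bond, no rebinding, instant escape: FPT ~ Exp(k_off)
        geo = single_bond_pure_unbinding
        k = CD_ADA.k_off0
        res = simulate_ensemble(
            [1], geometry=geo, force=0.0, t_window=1.0, t_max=1.0, n_replicates=100_000, seed=2
        )
        assert res.censored_fraction < 1e-3
        se = (1 / k) / math.sqrt(res.n_replicates)
        assert abs(res.mean_opening_time() - 1 / k) < 3 * se

    def test_max_of_iid_exponentials_harmonic_sum(self):
        # N pure-unbinding bonds at zero force: E[max] = (1/k) * H_N
        n = 8
        geo = pure_unbinding_geometry(n)
        res = simulate_ensemble(
            [1] * n, geometry=geo, force=0.0, t_window=0.1, t_max=0.1, n_replicates=50_000, seed=3
        )
        k = CD_ADA.k_off0
        h_n = sum(1.0 / i for i in range(1, n + 1))
        expected = h_n / k
        # SD of max of exponentials: sqrt(sum 1/(i k)^2)
        sd = math.sqrt(sum(1.0 / (i * k) ** 2 for i in range(1, n + 1)))
        assert res.censored_fraction < 1e-3
        assert abs(res.mean_opening_time() - expected) < 3 * sd / math.sqrt(res.n_replicates)

    def test_all_slow_gate_censored_in_actin_window(self):
        # eight slow bonds at ~1e-3 /s cannot all unbind and escape in 0.01 s;
        # union bound on even one unbinding event is ~8e-5 per replicate
        res = simulate_ensemble(
            [0] * 8, force=10.0, t_window=0.01, n_replicates=20_000, seed=4
        )
        assert res.opening_probability == 0.0
        assert res.censored_fraction == 1.0

    def test_gate_with_unbound_initial_state_rejected(self):
        gate = build_gate(MixtureSpec(p_fast=1.0), seed=0)
        gate.state[0] = 1  # UNBOUND
        with pytest.raises(ValueError):
            simulate_gate(gate)

    def test_nan_rate_names_offending_parameter(self):
        geo = GateGeometry(diffusion=DiffusionModel(D0=math.nan))
        gate = build_gate(MixtureSpec(p_fast=1.0), geometry=geo, seed=0)
        with pytest.raises(ConfigurationError, match="diffusion"):
            simulate_gate(gate, geometry=geo)


class TestOpeningProbability:
    def test_all_slow_mixture_probability_bounded(self):
        res = opening_probability(MixtureSpec(p_fast=0.0), n_replicates=100_000, seed=5)
        assert res.opening_probability == pytest.approx(0.0, abs=1e-5)
        assert res.ci95[1] < 1e-3

    def test_seeded_determinism(self):
        a = opening_probability(MixtureSpec(p_fast=0.5), n_replicates=2_000, seed=9)
        b = opening_probability(MixtureSpec(p_fast=0.5), n_replicates=2_000, seed=9)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.opened, b.opened)
        assert a.opening_probability == b.opening_probability

    def test_monotone_in_composition_force_and_window(self):
        kw = dict(n_replicates=20_000, seed=6)
        p_comp = [
            opening_probability(MixtureSpec(p), **kw).opening_probability
            for p in (0.5, 0.8, 1.0)
        ]
        assert p_comp[0] < p_comp[1] < p_comp[2]
        p_force = [
            opening_probability(MixtureSpec(0.8), force=f, **kw).opening_probability
            for f in (0.0, 50.0, 500.0)
        ]
        assert p_force[0] <= p_force[1] <= p_force[2]
        p_win = [
            opening_probability(MixtureSpec(0.8), t_window=w, **kw).opening_probability
            for w in (0.002, 0.01, 0.05)
        ]
        assert p_win[0] < p_win[1] < p_win[2]

    def test_estimate_unaffected_by_longer_t_max(self):
        a = opening_probability(MixtureSpec(0.8), n_replicates=5_000, seed=7)
        b = opening_probability(MixtureSpec(0.8), n_replicates=5_000, seed=7, t_max=0.05)
        assert a.opening_probability == b.opening_probability

    def test_ci_contains_point_estimate(self):
        res = opening_probability(MixtureSpec(0.8), n_replicates=5_000, seed=8)
        lo, hi = res.ci95
        assert lo <= res.opening_probability <= hi

    def test_summary_mentions_key_quantities(self):
        res = opening_probability(MixtureSpec(0.8, label="A80C20"), n_replicates=1_000, seed=1)
        text = res.summary()
        assert "A80C20" in text and "95% CI" in text


class TestKoffSweep:
    def test_mean_opening_time_decreases_with_koff(self):
        df = sweep_koff_fixed_Keq([1e1, 1e2, 1e3, 1e4], K_eq=1e5, n_replicates=3_000, seed=10)
        times = df["mean_open_time_s"].to_numpy()
        assert (np.diff(times) < 0).all()

    def test_detailed_balance_scaling_of_kon(self):
        df = sweep_koff_fixed_Keq([10.0, 30.0], K_eq=1e5, n_replicates=10, seed=0)
        assert df["k_on_per_M_s"].tolist() == pytest.approx([1e6, 3e6])

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            sweep_koff_fixed_Keq([], K_eq=1e5)
        with pytest.raises(ValueError):
            sweep_koff_fixed_Keq([0.0], K_eq=1e5)

    def test_censored_replicates_excluded_from_mean(self):
        # force heavy censoring with a tiny t_max
        df = sweep_koff_fixed_Keq(
            [1e1], K_eq=1e5, n_replicates=500, seed=11, t_max=0.01, t_window=0.01
        )
        assert df["censored_fraction"].iloc[0] > 0.9
        mean = df["mean_open_time_s"].iloc[0]
        assert math.isnan(mean) or mean <= 0.01


class TestMasterEquationOracle:
    def test_zero_bonds_always_open(self):
        p = master_equation_oracle([], t_grid=[0.0, 1.0])
        assert p == pytest.approx([1.0, 1.0])

    def test_single_bond_closed_form(self, single_bond_pure_unbinding):
        k = CD_ADA.k_off0
        t = np.array([1e-4, 1e-3, 5e-3])
        p = master_equation_oracle([1], geometry=single_bond_pure_unbinding, force=0.0, t_grid=t)
        assert p == pytest.approx(1.0 - np.exp(-k * t), rel=1e-5)

    def test_state_space_guard(self):
        with pytest.raises(ValueError, match="limited"):
            master_equation_oracle([1] * 5)

    @pytest.mark.parametrize("force", [0.0, 10.0, 102.0])
    def test_ssa_matches_oracle_on_four_bond_gate(self, force):
        geo = GateGeometry(n_units=4, valency=1)
        t_grid = np.array([5e-4, 2e-3, 5e-3, 1e-2])
        exact = master_equation_oracle([1, 1, 1, 1], geometry=geo, force=force, t_grid=t_grid)
        n = 20_000
        res = simulate_ensemble(
            [1, 1, 1, 1], geometry=geo, force=force, t_window=0.01, t_max=0.01,
            n_replicates=n, seed=12,
        )
        emp = np.array([np.mean(res.opened & (res.times <= t)) for t in t_grid])
        bound = 3.0 * np.sqrt(exact * (1.0 - exact) / n)
        assert (np.abs(emp - exact) <= np.maximum(bound, 3.0 / n)).all()

    def test_ssa_matches_oracle_on_two_bond_mixed_gate(self):
        # fast+slow pair, both chemistries sped up so the CDF is informative
        fast = HostGuestPair("f", k_on=1e8, k_off0=1e3)
        slow = HostGuestPair("s", k_on=1e5, k_off0=1e2)
        geo = GateGeometry(n_units=2, valency=1)
        t_grid = np.logspace(-3.5, -1.3, 6)
        exact = master_equation_oracle(
            [1, 0], fast_pair=fast, slow_pair=slow, geometry=geo, force=10.0, t_grid=t_grid
        )
        n = 100_000
        res = simulate_ensemble(
            [1, 0], fast_pair=fast, slow_pair=slow, geometry=geo, force=10.0,
            t_window=float(t_grid[-1]), t_max=float(t_grid[-1]), n_replicates=n, seed=13,
        )
        emp = np.array([np.mean(res.opened & (res.times <= t)) for t in t_grid])
        bound = 3.0 * np.sqrt(exact * (1.0 - exact) / n)
        assert (np.abs(emp - exact) <= np.maximum(bound, 3.0 / n)).all()
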