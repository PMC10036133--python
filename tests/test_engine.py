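import numpy as np
import pytest

from allocart import (
    CELL_SCHEDULE,
    FLOW_LOQ,
    DoseEvent,
    Drug,
    ExpansionCall,
    PopulationModel,
    RegimenSpec,
    TrajectoryBundle,
    alem_dose_stratum,
    classify_expansion,
    cv_to_omega,
    read_regimens,
    run_npc,
    sample_individual,
    simulate_subject,
    typical_subject,
)
from allocart.engine import PARAM_NAMES, registry_counts


class TestCVConversion:
    def test_zero_cv(self):
        assert cv_to_omega(0.0) == 0.0

    def test_printed_variability_conversion(self):
        """130% CV corresponds to omega = 0.9947 for a lognormal."""
        assert cv_to_omega(130.0) == pytest.approx(0.9947, abs=2e-4)

    def test_monte_carlo_cv_roundtrip(self):
        omega = cv_to_omega(130.0)
        rng = np.random.default_rng(0)
        draws = np.exp(rng.normal(0.0, omega, size=1_000_000))
        cv = draws.std() / draws.mean()
        assert cv == pytest.approx(1.30, rel=0.02)


class TestSampling:
    def test_zero_omegas_reproduce_typical(self, pop):
        frozen = PopulationModel(
            typical=dict(pop.typical),
            omega={k: 0.0 for k in pop.omega},
            fixed_flags=dict(pop.fixed_flags),
        )
        sp = sample_individual(frozen, 123)
        assert sp.values == pop.typical

    def test_seed_determinism(self, pop):
        a = sample_individual(pop, 42, draw_structural=True)
        b = sample_individual(pop, 42, draw_structural=True)
        assert a.values == b.values
        assert (a.allo_active, a.trunc_active) == (b.allo_active, b.trunc_active)

    def test_lognormal_median_equals_typical(self, pop):
        """Median of sampled values for a unit-omega parameter is the
        typical value (lognormal median identity), within 2%."""
        model = PopulationModel(
            typical=dict(pop.typical),
            omega={k: (1.0 if k == "CL" else 0.0) for k in pop.omega},
            fixed_flags=dict(pop.fixed_flags),
        )
        rng = np.random.default_rng(7)
        draws = [sample_individual(model, rng).values["CL"] for _ in range(50_000)]
        assert np.median(draws) == pytest.approx(pop.typical["CL"], rel=0.02)

    def test_correlated_block_requires_psd_matrix(self, pop):
        with pytest.raises(ValueError):
            PopulationModel(
                typical=dict(pop.typical),
                omega=dict(pop.omega),
                fixed_flags=dict(pop.fixed_flags),
                correlations=(["CL", "Q"], np.array([[1.0, 2.0], [2.0, 1.0]])),
            )


class TestRegistry:
    def test_structural_bookkeeping(self):
        counts = registry_counts()
        assert counts["n_parameters"] == 51
        assert counts["n_estimated"] == 18
        assert counts["n_iiv"] == 23

    def test_config_roundtrip(self, pop, tmp_path):
        path = tmp_path / "config.yaml"
        pop.to_yaml(path)
        loaded = PopulationModel.from_yaml(path)
        assert loaded.typical == pop.typical
        assert loaded.config_hash() == pop.config_hash()


class TestSimulateSubject:
    def test_zero_dose_gives_identically_zero_ucart(self, pop, reg40):
        events = [e for e in reg40.events if e.drug is not Drug.UCART19]
        reg = RegimenSpec(events=events)
        traj = simulate_subject(typical_subject(pop), reg)
        assert np.all(traj.ucart_blood == 0.0)

    def test_solver_tolerance_convergence(self, typical, reg40):
        """Halving solver tolerances moves Cmax by less than 0.1%."""
        t1 = simulate_subject(typical, reg40, rtol=1e-7)
        t2 = simulate_subject(typical, reg40, rtol=5e-8)
        c1 = t1.ucart_blood[t1.times > 0].max()
        c2 = t2.ucart_blood[t2.times > 0].max()
        assert abs(c1 - c2) / c2 < 1e-3

    def test_no_lymphodepletion_gives_flat_blq_profile(self, pop):
        reg = RegimenSpec(events=[DoseEvent(Drug.UCART19, 0.0, 6e6)])
        traj = simulate_subject(typical_subject(pop), reg)
        assert not classify_expansion(traj).expanded

    def test_observables_nonnegative_and_consistent(self, typical, reg40):
        traj = simulate_subject(typical, reg40)
        for name in ("alem", "fc", "host_nk_blood", "host_t_blood", "il7",
                     "ucart_blood", "lymphocytes"):
            assert np.all(getattr(traj, name) >= 0.0)
        assert np.allclose(
            traj.lymphocytes,
            traj.host_nk_blood + traj.host_t_blood + traj.ucart_blood,
        )


def make_traj(times, ucart):
    times = np.asarray(times, dtype=float)
    z = np.zeros_like(times)
    return TrajectoryBundle(
        times=times, states=np.zeros((11, times.size)), alem=z, fc=z,
        host_nk_blood=z, host_t_blood=z, il7=z,
        ucart_blood=np.asarray(ucart, dtype=float), lymphocytes=z,
    )


class TestClassifyExpansion:
    def test_all_zero_not_expanded(self):
        traj = make_traj(CELL_SCHEDULE, np.zeros(CELL_SCHEDULE.size))
        call = classify_expansion(traj)
        assert call == ExpansionCall(False, 0.0, call.tmax)

    def test_single_point_above_loq(self):
        ucart = np.zeros(CELL_SCHEDULE.size)
        ucart[CELL_SCHEDULE == 14.0] = 0.002
        call = classify_expansion(make_traj(CELL_SCHEDULE, ucart), loq=0.001)
        assert call.expanded and call.cmax == pytest.approx(0.002)
        assert call.tmax == 14.0

    def test_boundary_equal_to_loq_is_not_expansion(self):
        ucart = np.full(CELL_SCHEDULE.size, 0.001)
        assert not classify_expansion(make_traj(CELL_SCHEDULE, ucart), loq=0.001).expanded

    def test_short_trajectory_rejected(self):
        times = np.linspace(-7, 30, 20)
        with pytest.raises(ValueError):
            classify_expansion(make_traj(times, np.zeros(20)))


class TestNPC:
    def test_replicate_determinism(self, pop, study, study_covariates):
        a = run_npc(pop, study.regimens[:6], 3, seed=9,
                    covariates=study_covariates[:6])
        b = run_npc(pop, study.regimens[:6], 3, seed=9,
                    covariates=study_covariates[:6])
        assert np.array_equal(a.fractions, b.fractions)

    def test_deterministic_population_gives_zero_width_ci(self, pop, study, study_covariates):
        frozen = PopulationModel(
            typical=dict(pop.typical),
            omega={k: 0.0 for k in pop.omega},
            fixed_flags=dict(pop.fixed_flags),
        )
        res = run_npc(frozen, study.regimens[:8], 4, seed=1,
                      covariates=study_covariates[:8])
        assert res.ci90[0] == res.ci90[1]
        assert np.unique(res.fractions).size == 1

    def test_overall_fraction_is_weighted_stratum_mean(self, npc_result):
        total = np.zeros_like(npc_result.fractions)
        for name, fr in npc_result.strata.items():
            total += fr * npc_result.strata_n[name]
        assert np.allclose(total / npc_result.n_sets, npc_result.fractions)
        for fr in npc_result.strata.values():
            assert np.all((fr >= 0) & (fr <= 1))

    def test_no_alem_kill_means_no_expansion(self, pop, study, study_covariates):
        """Removing the alemtuzumab effect on host cells abolishes
        essentially all expansions even with allogeneic elimination on."""
        mod = PopulationModel(
            typical={**pop.typical, "k_effAlhostT": 0.0, "k_effAlhostNK": 0.0},
            omega=dict(pop.omega),
            fixed_flags=dict(pop.fixed_flags),
        )
        covs = [dict(c, allo_active=True, trunc_active=False)
                for c in study_covariates]
        res = run_npc(mod, study.regimens, 4, seed=3, covariates=covs)
        assert res.mean <= 0.02

    def test_expansion_fraction_monotone_in_k_allo(self, pop, study, study_covariates):
        means = []
        for factor in (0.3, 1.0, 3.0):
            mod = PopulationModel(
                typical={**pop.typical, "k_allo": pop.typical["k_allo"] * factor},
                omega=dict(pop.omega), fixed_flags=dict(pop.fixed_flags),
            )
            res = run_npc(mod, study.regimens, 12, seed=5,
                          covariates=study_covariates)
            means.append(res.mean)
        assert means[0] >= means[1] - 0.02 >= means[2] - 0.04

    def test_expansion_fraction_monotone_in_il7effmax(self, pop, study, study_covariates):
        means = []
        for factor in (0.2, 1.0, 5.0):
            mod = PopulationModel(
                typical={**pop.typical, "IL7effMax": pop.typical["IL7effMax"] * factor},
                omega=dict(pop.omega), fixed_flags=dict(pop.fixed_flags),
            )
            res = run_npc(mod, study.regimens, 12, seed=5,
                          covariates=study_covariates)
            means.append(res.mean)
        assert means[0] <= means[1] + 0.02 <= means[2] + 0.04


class TestDatasetInterface:
    def test_regimen_roundtrip_from_csv_tables(self, study):
        regimens, covs, ids = read_regimens(study.dosing, study.covariates)
        assert len(regimens) == 26 and len(ids) == 26
        for reg, orig in zip(regimens, study.regimens):
            assert reg.total_dose(Drug.ALEMTUZUMAB) == pytest.approx(
                orig.total_dose(Drug.ALEMTUZUMAB)
            )
            assert len(reg.events) == len(orig.events)
        assert all(set(c) >= {"allo_active", "dose_fractions", "refHostT"}
                   for c in covs)

    def test_stratum_assignment(self):
        assert alem_dose_stratum(RegimenSpec()) == "0mg"
        reg40 = RegimenSpec(events=[DoseEvent(Drug.ALEMTUZUMAB, -7.0, 40.0)])
        assert alem_dose_stratum(reg40) == "40mg"
        reg60 = RegimenSpec(events=[DoseEvent(Drug.ALEMTUZUMAB, -7.0, 60.0)])
        assert alem_dose_stratum(reg60) == "ge60mg"
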