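import numpy as np
import pytest
from scipy.integrate import solve_ivp

from allocart import (
    CELL_SCHEDULE,
    FLOW_LOQ,
    UCARTParams,
    UCARTState,
    classify_expansion,
    cmem_rate,
    cv_to_omega,
    derived_expansion_rates,
    initial_dose_split,
    safeguard_factor,
    scm_expansion_rate,
    simulate_subject,
    ucart_rhs,
)
from allocart.synthetic import archetype_profiles


class TestDoseSplit:
    def test_all_cells_in_scm(self):
        p = UCARTParams(dose_fractions=(1.0, 0.0, 0.0))
        scm, cm, em = initial_dose_split(p)
        assert cm == em == 0.0
        assert scm > 0

    def test_unit_conversion_to_g_per_l(self):
        """6e6 cells in 5 L of blood is 1.2e-3 G/L in total."""
        p = UCARTParams(nominal_dose=6e6, V_blood=5.0)
        assert sum(initial_dose_split(p)) == pytest.approx(1.2e-3)

    def test_equal_fractions_conserve_total(self):
        p = UCARTParams(dose_fractions=(1 / 3, 1 / 3, 1 / 3))
        scm, cm, em = initial_dose_split(p)
        assert scm == pytest.approx(cm) == pytest.approx(em)
        assert scm + cm + em == pytest.approx(p.nominal_dose / (p.V_blood * 1e9))

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            UCARTParams(dose_fractions=(0.5, 0.2, 0.2))


class TestExpansionRate:
    def test_without_il7_rate_is_log_fold_over_duration(self):
        p = UCARTParams()
        rate = scm_expansion_rate(0.0, p.T_exp_start + 1.0, p)
        assert rate == pytest.approx(np.log(p.xfoldUCART19preIL7) / p.T_exp)

    def test_hill_midpoint_multiplier(self):
        p = UCARTParams()
        rate = scm_expansion_rate(p.IL7_50, p.T_exp_start + 1.0, p)
        expected = np.log(
            p.xfoldUCART19preIL7 * (1 + p.IL7effMax / 2)
        ) / p.T_exp
        assert rate == pytest.approx(expected)

    def test_zero_outside_window(self):
        p = UCARTParams()
        assert scm_expansion_rate(50.0, p.T_exp_start - 0.1, p) == 0.0
        assert scm_expansion_rate(50.0, p.T_exp_start + p.T_exp + 0.1, p) == 0.0

    def test_derived_rates_are_fixed_shares(self):
        p = UCARTParams(expansionCMfromSCM=0.5, expansionEMfromSCM=0.25)
        assert derived_expansion_rates(0.0, p) == (0.0, 0.0)
        cm, em = derived_expansion_rates(2.0, p)
        assert cm == pytest.approx(1.0)
        assert em == pytest.approx(0.5)

    def test_rate_ordering_scm_cm_em(self):
        p = UCARTParams()
        scm = scm_expansion_rate(30.0, p.T_exp_start + 1.0, p)
        cm, em = derived_expansion_rates(scm, p)
        assert scm >= cm >= em


class TestSafeguard:
    @pytest.mark.parametrize("total, expected", [(0.0, 1.0), (50.0, 0.5), (100.0, 0.0), (150.0, 0.0)])
    def test_linear_brake(self, total, expected):
        assert safeguard_factor(total, UCARTParams(K_safeguard=100.0)) == pytest.approx(expected)

    def test_total_never_exceeds_capacity(self, pop):
        from allocart import typical_subject
        from allocart.synthetic import archetype_regimen

        sp = typical_subject(pop, allo_active=False).replace(
            k_inIL7=3.0, K_safeguard=5.0
        )
        traj = simulate_subject(sp, archetype_regimen(60.0))
        total = traj.states[5:].sum(axis=0)
        assert total.max() <= 5.0 * (1 + 1e-6)


class TestContractionSwitch:
    def test_limits_and_degenerate_case(self):
        p = UCARTParams(k_CMEM_high=0.3, k_CMEM_basal=0.01, t_persist=25.0)
        assert cmem_rate(0.0, p) == pytest.approx(0.3)
        assert cmem_rate(80.0, p) == pytest.approx(0.01)
        flat = UCARTParams(k_CMEM_high=0.1, k_CMEM_basal=0.1)
        for t in (0.0, 25.0, 60.0):
            assert cmem_rate(t, flat) == pytest.approx(0.1)


def integrate_ucart(p, y0, t_span, il7=0.0, host_t=0.0, t_eval=None):
    def rhs(t, y):
        state = UCARTState(*y)
        return ucart_rhs(state, t, p, il7, host_t, host_t)

    return solve_ivp(rhs, t_span, y0, rtol=1e-11, atol=1e-16, t_eval=t_eval,
                     method="LSODA")


class TestFullDynamics:
    def test_conservation_with_all_sinks_off(self):
        """Pure blood/tissue exchange conserves total cells to 1e-9."""
        p = UCARTParams(
            k_elimSCM=0.0, k_elimCM=0.0, k_elimEM=0.0,
            k_SCMCM=0.0, k_CMEM_high=0.0, k_CMEM_basal=0.0,
            xfoldUCART19preIL7=1.0, allo_active=False,
        )
        y0 = [1e-3, 0.0, 5e-4, 0.0, 2e-4, 0.0]
        sol = integrate_ucart(p, y0, (0, 100.0))
        assert sol.y[:, -1].sum() == pytest.approx(sum(y0), rel=1e-9)

    def test_huge_allogeneic_kill_keeps_profile_below_loq(self, pop, reg40):
        """Persistent host T with a strong allogeneic response: flat profile."""
        from allocart import typical_subject

        sp = typical_subject(pop).replace(k_effAlhostT=0.05, k_effAlhostNK=0.02,
                                          k_allo=500.0)
        traj = simulate_subject(sp, reg40)
        assert traj.ucart_blood[traj.times > 0].max() <= FLOW_LOQ

    def test_terminal_slope_matches_cm_eigenvalue_oracle(self):
        """Late decline is governed by the dominant eigenvalue of the
        T_CM blood/tissue block (elimination plus basal differentiation)."""
        p = UCARTParams(allo_active=False)
        A = np.array(
            [
                [-p.k_homingCM, p.k_egressCM],
                [p.k_homingCM, -(p.k_egressCM + p.k_elimCM + p.k_CMEM_basal)],
            ]
        )
        lam = np.linalg.eigvals(A).real.max()
        t0 = p.t_persist + 15.0
        t_eval = np.linspace(t0, t0 + 40.0, 20)
        sol = integrate_ucart(
            p, [0.0, 0.0, 0.02, 0.1, 0.0, 0.0], (t0, t0 + 40.0), t_eval=t_eval
        )
        blood = sol.y[2]
        slope = np.polyfit(t_eval[5:], np.log(blood[5:]), 1)[0]
        assert slope == pytest.approx(lam, rel=0.02)
        # in the tissue-dominant limit the slope is near k_elimCM + basal
        assert abs(slope) < p.k_elimCM + p.k_CMEM_basal

    def test_nonnegativity_under_random_parameters(self):
        rng = np.random.default_rng(11)
        for _ in range(15):
            p = UCARTParams(
                k_homingSCM=rng.uniform(0.5, 3), k_homingCM=rng.uniform(0.5, 3),
                k_homingEM=rng.uniform(0.5, 3), k_egressSCM=rng.uniform(0.05, 1),
                k_egressCM=rng.uniform(0.05, 1), k_egressEM=rng.uniform(0.05, 1),
                k_elimCM=rng.uniform(0, 0.1), k_elimEM=rng.uniform(0.1, 0.5),
                k_SCMCM=rng.uniform(0, 1), k_allo=rng.uniform(0, 30),
            )
            y0 = rng.uniform(0, 1e-3, size=6)
            sol = integrate_ucart(p, y0, (0, 60.0), il7=rng.uniform(0, 40),
                                  host_t=rng.uniform(0, 0.5))
            assert sol.y.min() > -1e-9


class TestProductComposition:
    def test_scm_removal_hurts_more_than_removing_cm_and_em(self, pop, reg40):
        """A product without stem-cell memory cells loses more exposure than
        one containing only them (SCM regenerates the other pools)."""
        from allocart import typical_subject

        base = archetype_profiles()["persistence"]
        no_scm = base.replace(dose_fractions=(1e-9, 2 / 3, 1 / 3 - 1e-9))
        only_scm = base.replace(dose_fractions=(1.0 - 2e-9, 1e-9, 1e-9))

        def auc(sp):
            traj = simulate_subject(sp, reg40)
            post = traj.times >= 0
            return np.trapezoid(traj.ucart_blood[post], traj.times[post])

        assert auc(no_scm) <= auc(only_scm)


class TestIL7AndAlloImpact:
    def test_higher_il7_potency_increases_cmax(self, pop, reg40):
        """Across the IIV range of IL7effMax, Cmax increases strictly."""
        from allocart import typical_subject

        omega = cv_to_omega(60.0)
        cmaxes = []
        for z in (-1.0, 0.0, 1.0):
            sp = typical_subject(pop).replace(
                IL7effMax=pop.typical["IL7effMax"] * np.exp(z * omega)
            )
            traj = simulate_subject(sp, reg40)
            cmaxes.append(traj.ucart_blood[traj.times > 0].max())
        assert cmaxes[0] < cmaxes[1] < cmaxes[2]

    def test_allo_switch_converts_persistence_to_transient(self, reg40):
        """Same subject, allogeneic elimination on/off: persistent profile
        becomes a transient peak that ends below the LOQ."""
        persistent = archetype_profiles()["persistence"]
        with_allo = persistent.replace(allo_active=True)
        t_off = simulate_subject(persistent, reg40)
        t_on = simulate_subject(with_allo, reg40)
        final_off = np.interp(84.0, t_off.times, t_off.ucart_blood)
        final_on = np.interp(84.0, t_on.times, t_on.ucart_blood)
        assert final_off > FLOW_LOQ
        assert final_on < FLOW_LOQ
        assert t_on.ucart_blood[t_on.times > 0].max() < t_off.ucart_blood.max()
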