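"""Toy receptor model: quadrature oracle, schedules, Metropolis sampler."""

import numpy as np
import pytest

from fepcycles import (
    FepInputError,
    LambdaSchedule,
    LigandTerm,
    ToyModelSpec,
    cim_scenario,
    estimate_leg,
    exact_leg_dg,
    exact_selectivity,
    gaussian_leg,
    sample_leg,
)
from fepcycles.energetics import R_KCAL
from fepcycles.toymodel import sample_equilibrium

RT = R_KCAL * 298.0


class TestSpecValidation:
    @pytest.mark.parametrize("kwargs", [
        {"barrier": 0.0}, {"barrier": -1.0}, {"half_width": 0.0},
        {"restraint": "left"}, {"temperature": -5.0},
    ])
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(FepInputError):
            ToyModelSpec(**kwargs)

    def test_negative_ligand_stiffness_rejected(self):
        with pytest.raises(FepInputError):
            LigandTerm(k=-1.0, x0=0.0)

    def test_basin_bias_sign(self):
        # positive bias lowers the active (x<0) basin
        spec = ToyModelSpec(basin_bias=2.0)
        assert spec.potential(-spec.half_width) < \
            spec.potential(spec.half_width)


class TestLambdaSchedule:
    def test_linear_grid(self):
        lam = LambdaSchedule.linear(50).global_lambdas()
        assert lam.size == 50
        assert lam[0] == 0.0 and lam[-1] == 1.0
        assert np.allclose(np.diff(lam), 1.0 / 49.0)

    def test_staged_grid_deduplicates_boundaries(self):
        lam = LambdaSchedule.staged((20, 20, 20, 20)).global_lambdas()
        assert lam.size == 4 * 20 - 3
        assert lam[0] == 0.0 and lam[-1] == 1.0
        assert np.all(np.diff(lam) > 0)

    @pytest.mark.parametrize("kwargs", [
        {"mode": "linear", "windows": 1},
        {"mode": "staged", "stages": ()},
        {"mode": "staged", "stages": (20, 1)},
        {"mode": "zigzag", "windows": 5},
    ])
    def test_invalid_schedule_rejected(self, kwargs):
        with pytest.raises(FepInputError):
            LambdaSchedule(**kwargs)


class TestExactLegDg:
    def test_identical_specs_give_zero(self):
        spec = ToyModelSpec(restraint="active_basin")
        assert exact_leg_dg(spec, spec) == pytest.approx(0.0, abs=1e-12)

    def test_pure_offset_gives_the_offset(self):
        spec = ToyModelSpec()
        shifted = spec.with_ligands([LigandTerm(k=0.0, x0=0.0, c=1.25)])
        assert exact_leg_dg(spec, shifted) == pytest.approx(1.25, abs=1e-9)

    def test_harmonic_ratio_closed_form(self):
        # near-zero barrier leaves a pure harmonic well:
        # ΔG = (RT/2)·ln(k2/k1)
        s1 = ToyModelSpec(barrier=1e-9,
                          ligand_terms=(LigandTerm(k=1.0, x0=0.0),))
        s2 = ToyModelSpec(barrier=1e-9,
                          ligand_terms=(LigandTerm(k=4.0, x0=0.0),))
        assert exact_leg_dg(s1, s2) == pytest.approx(
            0.5 * RT * np.log(4.0), abs=1e-7)

    def test_mismatched_restraints_rejected(self):
        with pytest.raises(FepInputError):
            exact_leg_dg(ToyModelSpec(restraint="active_basin"),
                         ToyModelSpec(restraint="inactive_basin"))


class TestExactSelectivity:
    base = ToyModelSpec()

    def test_symmetric_coupling_is_neutral(self):
        sym = self.base.with_ligands([LigandTerm(k=8.0, x0=0.0)])
        assert exact_selectivity(sym, sym, self.base) == 0.0

    def test_active_basin_agonist_is_positive(self):
        ago = self.base.with_ligands(
            [LigandTerm(k=8.0, x0=-self.base.half_width)])
        anta = self.base.with_ligands([LigandTerm(k=8.0, x0=0.0)])
        assert exact_selectivity(ago, anta, self.base) > 0

    def test_role_swap_negates_exactly(self):
        ago = self.base.with_ligands([LigandTerm(k=8.0, x0=-1.0)])
        anta = self.base.with_ligands([LigandTerm(k=8.0, x0=0.4)])
        fwd = exact_selectivity(ago, anta, self.base)
        rev = exact_selectivity(anta, ago, self.base)
        assert fwd == pytest.approx(-rev, abs=1e-9)

    def test_receptor_mismatch_rejected(self):
        other = ToyModelSpec(barrier=5.0).with_ligands(
            [LigandTerm(k=8.0, x0=0.0)])
        with pytest.raises(FepInputError):
            exact_selectivity(other, other, self.base)


class TestSampleLeg:
    base = ToyModelSpec(restraint="active_basin")

    def test_null_transformation_gives_exact_zero(self):
        leg = sample_leg(self.base, self.base, LambdaSchedule.linear(5),
                         n_samples=50, n_replicas=3, seed=1)
        for rep in leg.windows:
            for pair in rep:
                assert np.all(pair.du_from_i == 0.0)
                assert np.all(pair.du_from_j == 0.0)
        est = estimate_leg(leg)
        assert est.mean_dg == 0.0
        assert est.sem_dg == 0.0

    def test_constant_offset_telescopes_exactly(self):
        shifted = self.base.with_ligands([LigandTerm(k=0.0, x0=0.0, c=0.8)])
        leg = sample_leg(self.base, shifted, LambdaSchedule.linear(9),
                         n_samples=40, n_replicas=2, seed=2)
        est = estimate_leg(leg)
        assert est.mean_dg == pytest.approx(0.8, abs=1e-9)

    def test_deterministic_given_seed(self):
        kw = dict(schedule=LambdaSchedule.linear(6), n_samples=30,
                  n_replicas=2)
        end = self.base.with_ligands([LigandTerm(k=2.0, x0=-0.5)])
        leg_a = sample_leg(self.base, end, seed=9, **kw)
        leg_b = sample_leg(self.base, end, seed=9, **kw)
        leg_c = sample_leg(self.base, end, seed=10, **kw)
        for pa, pb in zip(leg_a.windows[0], leg_b.windows[0]):
            assert np.array_equal(pa.du_from_i, pb.du_from_i)
        assert not all(
            np.array_equal(pa.du_from_i, pc.du_from_i)
            for pa, pc in zip(leg_a.windows[0], leg_c.windows[0]))

    def test_replica_streams_are_independent(self):
        end = self.base.with_ligands([LigandTerm(k=2.0, x0=-0.5)])
        leg = sample_leg(self.base, end, LambdaSchedule.linear(4),
                         n_samples=40, n_replicas=2, seed=5)
        assert not np.array_equal(leg.windows[0][0].du_from_i,
                                  leg.windows[1][0].du_from_i)

    def test_annotations_follow_specs(self):
        end = self.base.with_ligands([LigandTerm(k=2.0, x0=-0.5)])
        leg = sample_leg(self.base, end, LambdaSchedule.linear(4),
                         n_samples=20, n_replicas=1, seed=3)
        assert leg.state_label == "Rstar"
        assert leg.environment == "bound"
        inact = ToyModelSpec(restraint="inactive_basin")
        leg2 = sample_leg(inact, inact.with_mutation(0.0, -1.0),
                          LambdaSchedule.linear(4), n_samples=20,
                          n_replicas=1, seed=3)
        assert leg2.state_label == "R"
        assert leg2.environment == "apo"

    def test_estimate_matches_quadrature_oracle(self):
        ago = self.base.with_ligands([LigandTerm(k=8.0, x0=-1.0)])
        anta = self.base.with_ligands([LigandTerm(k=8.0, x0=0.8)])
        leg = sample_leg(ago, anta, LambdaSchedule.linear(25),
                         n_samples=400, n_replicas=5, seed=42)
        est = estimate_leg(leg)
        exact = exact_leg_dg(ago, anta)
        assert abs(est.mean_dg - exact) < 3.0 * est.sem_dg

    def test_staged_and_linear_schedules_agree(self):
        # total ΔG is a state function: the λ path must not matter
        wt = self.base
        mut = wt.with_mutation(0.5, -2.0)
        lin = estimate_leg(sample_leg(wt, mut, LambdaSchedule.linear(21),
                                      n_samples=400, n_replicas=5, seed=8))
        stg = estimate_leg(sample_leg(wt, mut,
                                      LambdaSchedule.staged((6, 6, 6, 6)),
                                      n_samples=400, n_replicas=5, seed=9))
        err = np.hypot(lin.sem_dg, stg.sem_dg)
        assert abs(lin.mean_dg - stg.mean_dg) < 3.0 * max(err, 1e-3)

    def test_window_count_reduces_error(self):
        # a hard transformation (stiff ligand dragged across the basin)
        # estimated with more windows lands closer to the oracle
        ago = self.base.with_ligands([LigandTerm(k=60.0, x0=-1.6)])
        anta = self.base.with_ligands([LigandTerm(k=60.0, x0=-0.05)])
        exact = exact_leg_dg(ago, anta)
        errs = []
        for windows in (4, 40):
            est = estimate_leg(sample_leg(
                ago, anta, LambdaSchedule.linear(windows),
                n_samples=800, n_replicas=4, seed=0))
            errs.append(abs(est.mean_dg - exact))
        assert errs[-1] < errs[0]

    def test_acceptance_warning_metadata(self):
        # an absurdly stiff end state forces tiny acceptance somewhere
        stiff = self.base.with_ligands([LigandTerm(k=5e4, x0=-0.5)])
        leg = sample_leg(self.base, stiff, LambdaSchedule.linear(4),
                         n_samples=50, n_replicas=1, seed=4, step_scale=3.0)
        assert leg.metadata["acceptance_warnings"]


class TestSamplerEquilibrium:
    def test_boltzmann_histogram_matches_quadrature(self):
        # total-variation distance between sampled and exact densities
        spec = ToyModelSpec(barrier=2.0, basin_bias=1.0,
                            restraint="active_basin")
        xs = sample_equilibrium(spec, n_samples=500, n_chains=200, seed=17)
        assert xs.size == 100_000
        lo, hi = spec.domain()
        edges = np.linspace(lo, hi, 60)
        hist, _ = np.histogram(xs, bins=edges, density=True)
        centers = 0.5 * (edges[1:] + edges[:-1])
        beta = 1.0 / (R_KCAL * spec.temperature)
        dens = np.exp(-beta * spec.potential(centers))
        dens /= np.trapezoid(dens, centers)
        width = edges[1] - edges[0]
        tv = 0.5 * np.sum(np.abs(hist - dens)) * width
        assert tv < 0.05


class TestGaussianLeg:
    def test_zero_windows_recover_zero(self):
        est = estimate_leg(gaussian_leg([0.0, 0.0, 0.0], sigma=0.5,
                                        n_samples=2000, n_replicas=6,
                                        seed=1))
        assert abs(est.mean_dg) < 3.0 * max(est.sem_dg, 1e-4)

    def test_recovers_window_sum(self):
        est = estimate_leg(gaussian_leg([1.0, -0.5, 1.5], sigma=0.8,
                                        n_samples=10_000, n_replicas=10,
                                        seed=7))
        assert abs(est.mean_dg - 2.0) < 3.0 * est.sem_dg

    def test_degenerate_sigma_limit(self):
        est = estimate_leg(gaussian_leg([1.0, -0.5, 1.5], sigma=1e-6,
                                        n_samples=100, n_replicas=2,
                                        seed=3))
        assert est.mean_dg == pytest.approx(2.0, abs=1e-4)

    def test_invalid_inputs(self):
        with pytest.raises(FepInputError):
            gaussian_leg([], sigma=1.0, n_samples=10, n_replicas=1)
        with pytest.raises(FepInputError):
            gaussian_leg([1.0], sigma=0.0, n_samples=10, n_replicas=1)


class TestCimScenario:
    def test_quadrature_sign_pattern(self):
        # CIM: positive basal shift; deep binder amplified, shallow binder
        # compensated (affinity terms of opposite sign)
        sc = cim_scenario()

        def dg(restraint, ligand=None):
            s, e = sc.mutation_leg_specs(restraint, ligand)
            return exact_leg_dg(s, e)

        basal = dg("active_basin") - dg("inactive_basin")
        assert basal > 0
        aff_deep = dg("active_basin", "deep_agonist") - dg("active_basin")
        aff_shallow = dg("active_basin", "shallow_agonist") \
            - dg("active_basin")
        assert aff_deep > 0 > aff_shallow
        net_deep = basal + aff_deep
        net_shallow = basal + aff_shallow
        assert net_deep > basal > net_shallow
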