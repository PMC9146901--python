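"""Harmonic potential fitting, configuration volumes, generic-step averages."""
import json

import numpy as np
import pytest

from conftest import random_spd
from helixmech.curation import SELF_COMPLEMENTARY_DIMERS, UNIQUE_DIMERS
from helixmech.potentials import (
    DegeneratePotentialError,
    HarmonicStepPotential,
    PotentialSet,
    config_volume,
    dimer_from_tetramers,
    fit_potential,
    generic_mn,
    helical_repeat,
    step_energy,
)


class TestConfigVolume:
    def test_identity(self):
        assert config_volume(np.eye(6)) == pytest.approx(1.0)

    def test_diagonal(self):
        assert config_volume(np.diag([4, 4, 4, 1, 1, 1])) == pytest.approx(8.0)

    def test_matches_sqrt_det(self, rng):
        for _ in range(200):
            C = random_spd(rng)
            ref = np.sqrt(np.linalg.det(C))
            assert config_volume(C) == pytest.approx(ref, rel=1e-12)

    def test_negative_eigenvalue_rejected(self):
        C = np.eye(6)
        C[0, 0] = -1.0
        with pytest.raises(ValueError):
            config_volume(C)

    def test_tiny_negative_clipped(self):
        C = np.eye(6)
        C[5, 5] = -1e-14
        assert config_volume(C) == 0.0


class TestFitPotential:
    def test_identical_samples_degenerate(self):
        samples = np.tile([0, 0, 34, 0, 0, 3.4], (10, 1))
        pot = fit_potential(samples, "AA")
        assert pot.degenerate and pot.v_step == 0.0
        with pytest.raises(DegeneratePotentialError):
            pot.energy([0, 0, 35, 0, 0, 3.4])

    def test_two_point_sample_rank_one(self):
        theta = np.array([1.0, -2.0, 3.0, 0.1, -0.2, 0.3])
        pot = fit_potential(np.vstack([theta, -theta] * 5), "AA")
        assert np.allclose(pot.mean, 0.0)
        assert np.allclose(pot.cov, np.outer(theta, theta))
        assert pot.degenerate

    def test_parameter_recovery(self, rng):
        mu = np.array([-1.0, 3.0, 34.0, 0.1, -0.4, 3.35])
        sigma = random_spd(rng, scale=0.2)
        n = 5000
        draws = rng.multivariate_normal(mu, sigma, size=n)
        pot = fit_potential(draws, "AA")
        se = np.sqrt(np.diag(sigma) / n)
        assert np.all(np.abs(pot.mean - mu) < 3 * se)
        assert pot.v_step == pytest.approx(np.sqrt(np.linalg.det(sigma)), rel=0.05)

    def test_mean_self_energy_is_three_kt(self, rng):
        """Equipartition: six harmonic modes each hold kT/2 over the fitting
        sample (exact up to the n vs n-1 convention)."""
        draws = rng.multivariate_normal(np.zeros(6), random_spd(rng), size=5000)
        pot = fit_potential(draws, "AA")
        energies = [pot.energy(d) for d in draws]
        assert np.mean(energies) == pytest.approx(3.0, rel=0.02)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            fit_potential(np.zeros((5, 6)), "AA")


class TestStepEnergy:
    def test_zero_at_rest_state(self):
        pot = HarmonicStepPotential("AA", [0, 0, 34, 0, 0, 3.4], np.eye(6))
        assert step_energy(pot, [0, 0, 34, 0, 0, 3.4]) == 0.0

    def test_unit_displacement_half_kt(self):
        pot = HarmonicStepPotential("AA", [0, 0, 34, 0, 0, 3.4], np.eye(6))
        assert step_energy(pot, [0, 0, 35, 0, 0, 3.4]) == pytest.approx(0.5)

    def test_quadratic_form_oracle(self, rng):
        C = random_spd(rng)
        mean = rng.normal(size=6)
        pot = HarmonicStepPotential("AA", mean, C)
        F = np.linalg.inv(C)
        for _ in range(20):
            p = mean + rng.normal(size=6)
            ref = 0.5 * sum(
                F[i, j] * (p[i] - mean[i]) * (p[j] - mean[j])
                for i in range(6) for j in range(6)
            )
            assert step_energy(pot, p) == pytest.approx(ref, rel=1e-10)
            assert step_energy(pot, p) >= 0.0


class TestHelicalRepeat:
    def test_generic_step(self):
        assert float(f"{helical_repeat(34.1):.3g}") == 10.6

    @pytest.mark.parametrize("twist,expected", [(36.0, 10.0), (30.0, 12.0)])
    def test_exact_values(self, twist, expected):
        assert helical_repeat(twist) == pytest.approx(expected)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            helical_repeat(0.0)


class TestReflection:
    def test_reflected_potential_energy_matches_flipped_params(self, rng):
        C = random_spd(rng)
        pot = HarmonicStepPotential("AG", rng.normal(size=6), C)
        refl = pot.reflected()
        signs = np.array([-1, 1, 1, -1, 1, 1])
        for _ in range(10):
            p = rng.normal(size=6)
            assert refl.energy(p * signs) == pytest.approx(pot.energy(p), rel=1e-10)
        assert refl.v_step == pytest.approx(pot.v_step, rel=1e-10)

    def test_lookup_uses_complementary_reading(self, bdna_dimer_set):
        pot_ct = bdna_dimer_set.potential_for_dimer("CT")
        pot_ag = bdna_dimer_set.potential_for_dimer("AG")
        assert pot_ct.mean[0] == -pot_ag.mean[0]  # tilt
        assert pot_ct.mean[2] == pot_ag.mean[2]  # twist


class TestDimerFromTetramers:
    def test_identical_contexts_reduce_to_single(self, rng):
        C = random_spd(rng, scale=0.1)
        mean = np.array([0.5, 2.0, 34.0, -0.1, 0.2, 3.4])
        pots = {}
        from helixmech.curation import classify_tetramer

        for p in "ACGT":
            for f in "ACGT":
                lab = classify_tetramer(p, "AG", f)
                m = mean.copy()
                if lab[1:3] != "AG":  # stored under the complementary reading
                    m[0] *= -1
                    m[3] *= -1
                pots.setdefault(lab, HarmonicStepPotential(lab, m, C))
        tset = PotentialSet("tetramer", pots)
        avg, v = dimer_from_tetramers(tset, "AG")
        assert np.allclose(avg, mean, atol=1e-12)
        assert v == pytest.approx(config_volume(C), rel=1e-10)

    def test_two_twist_populations_average(self, bdna_tetramer_set):
        tset = bdna_tetramer_set.copy()
        from helixmech.curation import classify_tetramer

        labels = {classify_tetramer(p, "AT", f) for p in "ACGT" for f in "ACGT"}
        for i, lab in enumerate(sorted(labels)):
            tset.potentials[lab].mean[2] = 33.0 if i % 2 == 0 else 35.0
        avg, _ = dimer_from_tetramers(tset, "AT")
        assert avg[2] == pytest.approx(34.0)

    def test_missing_context_reported(self, bdna_tetramer_set):
        tset = bdna_tetramer_set.copy()
        del tset.potentials["AATA"]
        with pytest.raises(KeyError, match="AATA"):
            dimer_from_tetramers(tset, "AT")

    def test_requires_tetramer_level(self, bdna_dimer_set):
        with pytest.raises(ValueError):
            dimer_from_tetramers(bdna_dimer_set, "AT")


class TestGenericMN:
    def test_sequence_weighted_tilt_shift_cancel(self, bdna_dimer_set):
        g = generic_mn(bdna_dimer_set, "sequence-weighted")
        assert g.mean[0] == pytest.approx(0.0, abs=1e-12)
        assert g.mean[3] == pytest.approx(0.0, abs=1e-12)

    def test_modes_agree_for_shared_gaussian(self, rng):
        """All dimers drawn from one Gaussian: both averages recover it."""
        mu = np.array([0.0, 2.0, 34.1, 0.0, -0.1, 3.4])
        mu[0] = mu[3] = 0.0  # strand symmetry of the shared class
        C = np.diag([9.0, 16.0, 16.0, 0.1, 0.2, 0.05])
        pset = PotentialSet(
            "dimer",
            {d: HarmonicStepPotential(d, mu.copy(), C.copy()) for d in UNIQUE_DIMERS},
        )
        g_seq = generic_mn(pset, "sequence-weighted")
        samples = {
            d: rng.multivariate_normal(mu, C, size=400) for d in UNIQUE_DIMERS
        }
        g_str = generic_mn(
            mode="structure-weighted", samples_by_class=samples, seed=3,
            replicates=30,
        )
        assert np.allclose(g_seq.mean, mu)
        assert np.max(np.abs(g_str.mean - mu)) < 0.5  # within sampling error
        assert g_str.v_step == pytest.approx(g_seq.v_step, rel=0.15)

    def test_pooled_volume_below_average_volume_for_scale_mixture(self, rng):
        """Classes sharing a mean but differing in spread: the volume of the
        pooled cloud is below the average of class volumes (power-mean
        inequality on the covariance scales)."""
        mu = np.zeros(6)
        base = np.diag([9.0, 16.0, 16.0, 0.1, 0.2, 0.05])
        scales = {d: 0.4 + 0.2 * i for i, d in enumerate(UNIQUE_DIMERS)}
        pset = PotentialSet(
            "dimer",
            {d: HarmonicStepPotential(d, mu, base * s**2) for d, s in scales.items()},
        )
        g_seq = generic_mn(pset, "sequence-weighted")
        samples = {
            d: rng.multivariate_normal(mu, base * scales[d] ** 2, size=500)
            for d in UNIQUE_DIMERS
        }
        g_str = generic_mn(
            mode="structure-weighted", samples_by_class=samples, seed=5,
            replicates=30,
        )
        assert g_str.v_step < g_seq.v_step

    def test_structure_mode_needs_replicates(self, rng):
        samples = {d: rng.normal(size=(50, 6)) for d in UNIQUE_DIMERS}
        with pytest.raises(ValueError):
            generic_mn(mode="structure-weighted", samples_by_class=samples,
                       seed=0, replicates=1)

    def test_reproducible_with_seed(self, rng):
        samples = {d: rng.normal(size=(60, 6)) for d in UNIQUE_DIMERS}
        a = generic_mn(mode="structure-weighted", samples_by_class=samples,
                       seed=9, replicates=5)
        b = generic_mn(mode="structure-weighted", samples_by_class=samples,
                       seed=9, replicates=5)
        assert np.array_equal(a.mean, b.mean) and a.v_step == b.v_step


class TestSerialization:
    def test_json_round_trip(self, bdna_dimer_set, tmp_path):
        p = tmp_path / "set.json"
        bdna_dimer_set.to_json(p)
        back = PotentialSet.from_json(p)
        assert back.level == "dimer"
        assert set(back.potentials) == set(bdna_dimer_set.potentials)
        for k in back.potentials:
            assert np.allclose(back.potentials[k].mean,
                               bdna_dimer_set.potentials[k].mean)
            assert np.allclose(back.potentials[k].cov,
                               bdna_dimer_set.potentials[k].cov)

    def test_csv_round_trip(self, bdna_dimer_set, tmp_path):
        p = tmp_path / "set.csv"
        bdna_dimer_set.to_csv(p)
        back = PotentialSet.from_csv(p, "dimer")
        for k in bdna_dimer_set.potentials:
            assert np.allclose(back.potentials[k].cov,
                               bdna_dimer_set.potentials[k].cov, atol=1e-9)

    def test_schema_version_recorded(self, bdna_dimer_set):
        obj = json.loads(bdna_dimer_set.to_json())
        assert obj["schema"] == 1

    def test_level_capacity_enforced(self):
        pots = {f"L{i}": HarmonicStepPotential(f"L{i}", np.zeros(6), np.eye(6))
                for i in range(11)}
        with pytest.raises(ValueError):
            PotentialSet("dimer", pots)


def test_derive_potential_set_from_synthetic_table(small_ensemble):
    from helixmech.potentials import derive_potential_set
    from helixmech.synth import bdna_means

    pset = derive_potential_set(small_ensemble, "dimer")
    assert set(pset.potentials) == set(UNIQUE_DIMERS)
    for d in SELF_COMPLEMENTARY_DIMERS:
        assert pset.potentials[d].mean[0] == pytest.approx(0.0, abs=1e-12)
        assert pset.potentials[d].mean[3] == pytest.approx(0.0, abs=1e-12)
    # culled moments land near the generating tables (3-sd culling trims
    # the tails, so volumes shrink; means stay close)
    for d in ("AT", "TA"):
        gen = bdna_means(d)
        assert np.abs(pset.potentials[d].mean[2] - gen[2]) < 0.6
    assert pset.potentials["AT"].v_step < pset.potentials["TA"].v_step
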