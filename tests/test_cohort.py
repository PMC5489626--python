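"""Synthetic cohort generator: distributions, closure and determinism."""

import dataclasses
import math

import numpy as np
import pytest

from pigletgfr import (
    AgeGroupSpec,
    KineticsSpec,
    SimulationConfig,
    allometric_bsa,
    apply_bw_exclusion,
    calibrate_bsa_k,
    creatinine_clearance,
    generate_cohort,
    iohexol_clearance,
    simulate_iohexol_profile,
    simulate_plasma_samples,
    simulate_urine_collections,
)
from pigletgfr.errors import ConfigurationError, DomainError, SchemaError

#: (BW kg, BSA m^2) group means used to calibrate the allometric surface law.
BW_BSA_MEANS = [(2.01, 0.16), (10.0, 0.46), (13.9, 0.59), (112.88, 2.42)]


def _single_group_config(group: AgeGroupSpec, seed: int = 0, **kwargs) -> SimulationConfig:
    return SimulationConfig(groups=(group,), seed=seed, **kwargs)


class TestGenerateCohort:
    def test_sample_means_track_group_means(self, groups):
        """At n=200, every metric's mean lies within 3 SE of its target."""
        g = dataclasses.replace(groups[2], n=200)
        cohort = generate_cohort(_single_group_config(g, seed=3))
        for attr, mean, sd in [
            ("bw_kg", g.bw_mean, g.bw_sd),
            ("kw_g", g.kw_mean, g.kw_sd),
            ("pcr_mg_dl", g.pcr_mean, g.pcr_sd),
            ("total_protein_g_per_l", g.tp_mean, g.tp_sd),
        ]:
            vals = [getattr(s, attr) for s in cohort]
            assert abs(np.mean(vals) - mean) < 3 * sd / math.sqrt(g.n), attr

    def test_study_sized_group_mean_bodyweight(self, groups):
        """A 16-piglet 7-week group reproduces its 13.9 kg mean within 3 SE."""
        g = groups[2]
        cohort = generate_cohort(_single_group_config(g, seed=11))
        assert len(cohort) == 16
        bw = [s.bw_kg for s in cohort]
        assert abs(np.mean(bw) - g.bw_mean) < 3 * g.bw_sd / math.sqrt(g.n)

    def test_zero_sd_collapses_to_group_means(self, groups):
        g = dataclasses.replace(
            groups[0], bw_sd=0.0, kw_sd=0.0, pcr_sd=0.0, tp_sd=0.0, n=5
        )
        cohort = generate_cohort(_single_group_config(g, gfr_log_sd=0.0))
        assert all(s.bw_kg == g.bw_mean for s in cohort)
        assert all(s.kw_g == g.kw_mean for s in cohort)
        assert all(s.pcr_mg_dl == g.pcr_mean for s in cohort)
        assert all(s.total_protein_g_per_l == g.tp_mean for s in cohort)
        assert len({s.true_gfr_ml_min for s in cohort}) == 1

    def test_same_seed_same_cohort(self, default_config):
        first = generate_cohort(default_config)
        second = generate_cohort(default_config)
        assert first == second

    def test_different_seed_different_cohort(self, default_config):
        other = dataclasses.replace(default_config, seed=default_config.seed + 1)
        assert generate_cohort(default_config) != generate_cohort(other)

    def test_invalid_group_rejected(self):
        with pytest.raises(ConfigurationError):
            AgeGroupSpec(8, 0, 2.0, 0.4, 0.16, 0.02, 14, 3, 0.43, 0.08, 28, 5)
        with pytest.raises(ConfigurationError):
            AgeGroupSpec(8, 5, -2.0, 0.4, 0.16, 0.02, 14, 3, 0.43, 0.08, 28, 5)


class TestAllometricBsa:
    def test_unit_bodyweight_returns_coefficient(self):
        assert allometric_bsa(1.0, 0.123, 2 / 3) == pytest.approx(0.123)

    def test_calibrated_law_matches_group_surface_areas(self):
        """k from log-log least squares reproduces the mean BSAs within 5%.

        Oracle: closed-form least squares of log(BSA) - e*log(BW) over the
        four group mean pairs, computed here independently.
        """
        e = 2 / 3
        k_oracle = math.exp(
            np.mean([math.log(bsa) - e * math.log(bw) for bw, bsa in BW_BSA_MEANS])
        )
        assert calibrate_bsa_k(BW_BSA_MEANS, e) == pytest.approx(k_oracle, rel=1e-12)
        assert allometric_bsa(10.0, k_oracle, e) == pytest.approx(0.46, rel=0.05)
        assert allometric_bsa(112.88, k_oracle, e) == pytest.approx(2.42, rel=0.05)

    def test_nonpositive_bodyweight_rejected(self):
        with pytest.raises(DomainError):
            allometric_bsa(0.0, 0.1, 2 / 3)


class TestIohexolProfile:
    def _subject(self, default_config):
        return generate_cohort(default_config)[0]

    def test_noise_free_profile_is_exact_biexponential(
        self, default_config, kinetics, rng
    ):
        """With zero CV the profile equals A e^-at + B e^-bt with dose/AUC = CL."""
        s = self._subject(default_config)
        cl = 40.0
        prof = simulate_iohexol_profile(
            s, 64.7, cl, kinetics, default_config.sampling_schedule_min, 0.0, rng, 0.9
        )
        auc = prof.total_dose_mg * 0.9 * 1000.0 / cl
        A = kinetics.fast_fraction * auc * kinetics.alpha_per_min
        B = (1 - kinetics.fast_fraction) * auc * kinetics.beta_per_min
        t = np.asarray(prof.times_min[1:])
        expected = A * np.exp(-kinetics.alpha_per_min * t) + B * np.exp(
            -kinetics.beta_per_min * t
        )
        np.testing.assert_allclose(prof.conc_ug_ml[1:], expected, rtol=1e-12)
        assert A / kinetics.alpha_per_min + B / kinetics.beta_per_min == pytest.approx(
            auc, rel=1e-12
        )

    def test_equal_rates_collapse_to_monoexponential(
        self, default_config, mono_kinetics, rng
    ):
        s = self._subject(default_config)
        cl = 25.0
        prof = simulate_iohexol_profile(
            s, 64.7, cl, mono_kinetics, default_config.sampling_schedule_min, 0.0, rng, 1.0
        )
        beta = mono_kinetics.beta_per_min
        c0 = prof.total_dose_mg * 1000.0 * beta / cl
        t = np.asarray(prof.times_min[1:])
        np.testing.assert_allclose(prof.conc_ug_ml[1:], c0 * np.exp(-beta * t), rtol=1e-12)

    def test_predose_concentration_exactly_zero(self, default_config, kinetics, rng):
        s = self._subject(default_config)
        prof = simulate_iohexol_profile(
            s, 64.7, 50.0, kinetics, default_config.sampling_schedule_min, 0.3, rng
        )
        assert prof.times_min[0] == 0.0 and prof.conc_ug_ml[0] == 0.0

    def test_schedule_without_predose_rejected(self, default_config, kinetics, rng):
        s = self._subject(default_config)
        with pytest.raises(SchemaError):
            simulate_iohexol_profile(s, 64.7, 50.0, kinetics, (5, 15, 30), 0.0, rng)

    def test_nca_mean_unbiased_under_assay_noise(self, default_config, kinetics):
        """Monte Carlo: mean NCA clearance over 1000 noisy replicates within 2%."""
        s = self._subject(default_config)
        true_cl = 50.0
        recovered = []
        for i in range(1000):
            rng = np.random.default_rng([9, i])
            prof = simulate_iohexol_profile(
                s, 64.7, true_cl, kinetics, default_config.sampling_schedule_min,
                0.05, rng, 0.9,
            )
            recovered.append(iohexol_clearance(prof).clearance_ml_min)
        assert np.mean(recovered) == pytest.approx(true_cl, rel=0.02)


class TestUrineCollections:
    def test_mass_balance_hand_value(self, default_config, rng):
        """CL=50, Pcr=0.45, T=60 min => U_cr * U_vol = 1350 mg*mL/dL."""
        s = generate_cohort(default_config)[0]
        (coll,) = simulate_urine_collections(s, 50.0, 0.45, [(600, 660)], 0.0, rng)
        assert coll.u_cr_mg_dl * coll.u_vol_ml == pytest.approx(1350.0, rel=1e-12)

    def test_noise_free_collections_invert_exactly(self, default_config, rng):
        s = generate_cohort(default_config)[0]
        colls = simulate_urine_collections(
            s, 37.5, s.pcr_mg_dl, default_config.urine_intervals, 0.0, rng
        )
        for c in colls:
            assert creatinine_clearance(
                c.u_cr_mg_dl, c.u_vol_ml, s.pcr_mg_dl, c.t_min
            ) == pytest.approx(37.5, rel=1e-12)

    def test_one_collection_per_interval(self, default_config, rng):
        s = generate_cohort(default_config)[0]
        colls = simulate_urine_collections(
            s, 10.0, 0.5, default_config.urine_intervals, 0.1, rng
        )
        assert len(colls) == 3

    def test_nonpositive_clearance_rejected(self, default_config, rng):
        s = generate_cohort(default_config)[0]
        with pytest.raises(DomainError):
            simulate_urine_collections(s, 0.0, 0.5, [(0, 60)], 0.0, rng)


class TestBodyweightExclusion:
    def test_partition_is_exhaustive_and_disjoint(self, default_config):
        cohort = generate_cohort(default_config)
        kept, withdrawn = apply_bw_exclusion(cohort, 10.0)
        assert len(kept) + len(withdrawn) == len(cohort)
        assert {s.subject_id for s in kept}.isdisjoint(s.subject_id for s in withdrawn)
        assert all(s.bw_kg >= 10.0 for s in kept)
        assert all(s.bw_kg < 10.0 for s in withdrawn)

    def test_threshold_example(self, default_config):
        base = generate_cohort(default_config)[0]
        cohort = [dataclasses.replace(base, bw_kg=w) for w in (1.2, 1.6, 2.0)]
        kept, withdrawn = apply_bw_exclusion(cohort, 1.50)
        assert [s.bw_kg for s in kept] == [1.6, 2.0]
        assert [s.bw_kg for s in withdrawn] == [1.2]

    def test_tiny_threshold_keeps_all(self, default_config):
        cohort = generate_cohort(default_config)
        kept, withdrawn = apply_bw_exclusion(cohort, 1e-9)
        assert len(kept) == len(cohort) and not withdrawn

    def test_two_of_sixteen_withdrawn_leaves_fourteen(self, default_config):
        """An enrolment of 16 with 2 underweight reproduces the 14-strong group."""
        base = generate_cohort(default_config)[0]
        weights = [1.2, 1.4] + [1.6 + 0.1 * i for i in range(14)]
        cohort = [dataclasses.replace(base, bw_kg=w) for w in weights]
        kept, withdrawn = apply_bw_exclusion(cohort, 1.50)
        assert (len(kept), len(withdrawn)) == (14, 2)


class TestPlasmaSamples:
    def test_jaffe_reading_depressed_by_protein_error(self, default_config, rng):
        s = generate_cohort(default_config)[0]
        samples = simulate_plasma_samples(s, 0.0, rng)
        jaffe = [x.p_cr_mg_dl for x in samples if x.assay == "jaffe"]
        enz = [x.p_cr_mg_dl for x in samples if x.assay == "enzymatic"]
        assert all(j < e for j, e in zip(jaffe, enz))
        assert all(e == pytest.approx(s.pcr_mg_dl) for e in enz)

    def test_three_times_of_day_per_assay(self, default_config, rng):
        s = generate_cohort(default_config)[0]
        samples = simulate_plasma_samples(s, 0.05, rng)
        assert sum(1 for x in samples if x.assay == "jaffe") == 3
        assert sum(1 for x in samples if x.assay == "enzymatic") == 3


class TestConfigValidation:
    def test_nonmonotone_schedule_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(sampling_schedule_min=(0, 10, 5))

    def test_schedule_must_start_at_zero(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(sampling_schedule_min=(5, 10, 20))

    def test_assay_cv_bounds(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(assay_cv=1.0)

    def test_kinetics_requires_alpha_at_least_beta(self):
        with pytest.raises(ConfigurationError):
            KineticsSpec(alpha_per_min=0.001, beta_per_min=0.004)
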