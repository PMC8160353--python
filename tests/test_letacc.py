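"""Voxelized dose and dose-averaged LET accumulation."""

import logging

import numpy as np
import pytest

from microdose import (ConfigurationError, DegenerateInputError, DomainError,
                       StepDeposit, StoppingPowerTable, accumulate,
                       analytic_dose_averaged_let, dose_uncertainty,
                       let_uncertainty, lookup_stopping_power, mask_low_dose,
                       read_step_log, read_stopping_power, synth_step_log,
                       write_step_log)

FLAT = StoppingPowerTable("p", np.array([1.0, 100.0]), np.array([10.0, 10.0]))
# log-log linear interpolation is exact on the power law S = E
IDENTITY = StoppingPowerTable("p", np.array([0.01, 1000.0]),
                              np.array([0.01, 1000.0]))


def step(ek, ed, voxel=(0, 0, 0), hist=0, kind="p"):
    return StepDeposit(voxel_index=voxel, history_id=hist, particle_kind=kind,
                       kinetic_energy=ek, deposited_energy=ed)


class TestLookup:
    def test_flat_table(self):
        assert lookup_stopping_power(FLAT, 10.0) == pytest.approx(10.0)

    def test_power_law_exact(self):
        table = StoppingPowerTable("p", np.array([1.0, 100.0]),
                                   np.array([1.0, 100.0]))
        assert lookup_stopping_power(table, 10.0) == pytest.approx(10.0, rel=1e-12)

    def test_clamp_warns(self, caplog):
        with caplog.at_level(logging.WARNING):
            val = lookup_stopping_power(FLAT, 0.5)
        assert val == pytest.approx(10.0)
        assert "clamped" in caplog.text

    def test_nonpositive_energy_rejected(self):
        with pytest.raises(DomainError):
            lookup_stopping_power(FLAT, 0.0)


class TestAccumulate:
    def test_hand_arithmetic(self):
        steps = [step(2.0, 1.0), step(4.0, 3.0, hist=1)]
        tally = accumulate(steps, {"p": IDENTITY}, (1, 1, 1))
        assert tally.let[0, 0, 0] == pytest.approx((1 * 2 + 3 * 4) / 4.0)

    def test_single_step_identity(self):
        tally = accumulate([step(7.0, 2.5)], {"p": IDENTITY}, (1, 1, 1))
        assert tally.let[0, 0, 0] == pytest.approx(7.0, rel=1e-12)

    def test_brute_force_oracle_exact(self, rng):
        shape = (3, 2, 4)
        steps = []
        for _ in range(1000):
            voxel = tuple(int(rng.integers(0, s)) for s in shape)
            steps.append(step(float(rng.uniform(0.1, 500)),
                              float(rng.uniform(0.0, 2.0)), voxel=voxel,
                              hist=int(rng.integers(0, 50))))
        tally = accumulate(steps, {"p": IDENTITY}, shape)
        from microdose.letacc import _canonical_order
        num = np.zeros(shape)
        den = np.zeros(shape)
        # brute-force recomputation in the same canonical order is bit-exact
        for s in _canonical_order(steps):
            sel = lookup_stopping_power(IDENTITY, s.kinetic_energy)
            num[s.voxel_index] += s.deposited_energy * sel
            den[s.voxel_index] += s.deposited_energy
        expect = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
        assert np.array_equal(np.nan_to_num(tally.let), np.nan_to_num(expect))

    def test_order_independence_bit_identical(self, rng):
        steps = [step(float(rng.uniform(1, 50)), float(rng.uniform(0, 1)),
                      voxel=(int(rng.integers(0, 2)), 0, 0),
                      hist=int(rng.integers(0, 5))) for _ in range(200)]
        shuffled = list(steps)
        rng.shuffle(shuffled)
        t1 = accumulate(steps, {"p": IDENTITY}, (2, 1, 1))
        t2 = accumulate(shuffled, {"p": IDENTITY}, (2, 1, 1))
        assert np.array_equal(t1.sum_ed, t2.sum_ed)
        assert np.array_equal(t1.sum_ed_s, t2.sum_ed_s)
        assert np.array_equal(t1.sum_x2, t2.sum_x2)

    def test_mixing_bound(self, rng):
        steps = [step(float(rng.uniform(1, 80)), float(rng.uniform(0.1, 1)))
                 for _ in range(100)]
        tally = accumulate(steps, {"p": IDENTITY}, (1, 1, 1))
        assert tally.let_step_min[0, 0, 0] <= tally.let[0, 0, 0] \
            <= tally.let_step_max[0, 0, 0]

    def test_missing_table_names_kind(self):
        with pytest.raises(ConfigurationError, match="electron"):
            accumulate([step(1.0, 1.0, kind="electron")], {"p": FLAT}, (1, 1, 1))

    def test_kind_restriction_filters_let_sums(self):
        steps = [step(2.0, 1.0, kind="primary"), step(50.0, 5.0, kind="delta")]
        tally = accumulate(steps, {"primary": IDENTITY, "delta": IDENTITY},
                           (1, 1, 1), kinds={"primary"})
        assert tally.let[0, 0, 0] == pytest.approx(2.0)
        assert tally.dose[0, 0, 0] == pytest.approx(6.0)  # dose still counts all


class TestUncertainty:
    def test_identical_histories_zero(self):
        steps = [step(1.0, 2.0, hist=h) for h in range(4)]
        rel = dose_uncertainty(accumulate(steps, {"p": IDENTITY}, (1, 1, 1)))
        assert rel[0, 0, 0] == 0.0

    def test_two_history_hand_value(self):
        steps = [step(1.0, 1.0, hist=0), step(1.0, 3.0, hist=1)]
        rel = dose_uncertainty(accumulate(steps, {"p": IDENTITY}, (1, 1, 1)))
        assert rel[0, 0, 0] == pytest.approx(0.5)

    def test_single_history_rejected(self):
        tally = accumulate([step(1.0, 1.0)], {"p": IDENTITY}, (1, 1, 1))
        with pytest.raises(DegenerateInputError):
            dose_uncertainty(tally)

    def test_one_over_sqrt_n_scaling(self, rng):
        """With fixed steps per history, sigma_rel falls like 1/sqrt(N)."""
        rels = []
        for n_hist in (100, 1000, 10_000):
            steps = [step(1.0, float(rng.uniform(0.5, 1.5)), hist=h)
                     for h in range(n_hist) for _ in range(5)]
            tally = accumulate(steps, {"p": IDENTITY}, (1, 1, 1))
            rels.append(dose_uncertainty(tally)[0, 0, 0])
        assert rels[0] / rels[1] == pytest.approx(np.sqrt(10), rel=0.3)
        assert rels[1] / rels[2] == pytest.approx(np.sqrt(10), rel=0.3)

    def test_let_uncertainty_doubles(self):
        assert let_uncertainty(0.01) == pytest.approx(0.02)
        assert let_uncertainty(0.0) == 0.0
        assert np.allclose(let_uncertainty(np.array([0.01, 0.03])), [0.02, 0.06])


class TestMask:
    def _tally(self, doses):
        steps = [step(1.0, d, voxel=(i, 0, 0), hist=i)
                 for i, d in enumerate(doses)]
        return accumulate(steps, {"p": IDENTITY}, (len(doses), 1, 1))

    def test_low_dose_voxel_masked(self):
        profile = mask_low_dose(self._tally([100.0, 0.05, 50.0]), 0.001)
        assert list(profile.mask[:, 0, 0]) == [False, True, False]
        assert np.isnan(profile.let[1, 0, 0])

    def test_zero_fraction_masks_nothing(self):
        profile = mask_low_dose(self._tally([100.0, 0.05, 50.0]), 0.0)
        assert not profile.mask.any()

    def test_uniform_dose_masks_nothing(self):
        profile = mask_low_dose(self._tally([1.0, 1.0, 1.0]), 0.001)
        assert not profile.mask.any()

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateInputError):
            mask_low_dose(self._tally([0.0, 0.0]), 0.001)


class TestAnalyticOracle:
    def test_single_energy(self):
        assert analytic_dose_averaged_let([(7.0, 1.0)], IDENTITY) == pytest.approx(7.0)

    def test_equal_weight_mean(self):
        assert analytic_dose_averaged_let([(2.0, 1.0), (4.0, 1.0)],
                                          IDENTITY) == pytest.approx(3.0)

    def test_zero_weight_rejected(self):
        with pytest.raises(DegenerateInputError):
            analytic_dose_averaged_let([(2.0, 0.0)], IDENTITY)

    def test_synthetic_log_converges_to_quadrature(self):
        spectrum = [(2.0, 0.3), (40.0, 0.7)]
        expected = analytic_dose_averaged_let(spectrum, IDENTITY)
        steps = synth_step_log(spectrum, n_steps=100_000, n_histories=100,
                               shape=(2, 2, 2), kind="p", seed=7)
        tally = accumulate(steps, {"p": IDENTITY}, (2, 2, 2))
        total = tally.sum_ed_s.sum() / tally.sum_ed.sum()
        assert total == pytest.approx(expected, rel=0.01)

    def test_single_energy_log_exact_everywhere(self):
        steps = synth_step_log([(5.0, 1.0)], n_steps=2000, n_histories=10,
                               shape=(2, 2, 1), kind="p", seed=3)
        tally = accumulate(steps, {"p": IDENTITY}, (2, 2, 1))
        assert np.allclose(tally.let, 5.0)


class TestBenchmarkRatios:
    def test_let_ratios_at_plateau(self):
        """300 MeV electron Ld over other beams rounds to the published ratios."""
        from microdose.reference import ld_ratios_vs_300mev
        r = ld_ratios_vs_300mev("4cm")
        assert round(r["194 MeV/n carbon ions"], 2) == 0.04
        assert round(r["105 MeV protons"], 1) == 0.2
        assert round(r["100 MeV electrons"], 1) == 1.9
        assert round(r["20 MeV electrons"], 1) == 3.2
        assert round(r["Co-60 gammas"], 1) == 2.4

    def test_yd_over_ld_at_plateau(self):
        from microdose.reference import yd_over_ld_4cm
        r = yd_over_ld_4cm()
        assert round(r["Co-60 gammas"], 1) == 5.4
        assert round(r["20 MeV electrons"], 1) == 5.1


class TestStepLogIO:
    def test_round_trip(self, tmp_path, rng):
        steps = [step(float(rng.uniform(1, 50)), float(rng.uniform(0, 1)),
                      voxel=(int(rng.integers(0, 2)), 0, 0),
                      hist=int(rng.integers(0, 5))) for _ in range(20)]
        path = tmp_path / "steps.tsv"
        write_step_log(path, steps, (2, 1, 1))
        back, shape = read_step_log(path)
        assert shape == (2, 1, 1)
        assert len(back) == 20
        t1 = accumulate(steps, {"p": IDENTITY}, shape)
        t2 = accumulate(back, {"p": IDENTITY}, shape)
        assert np.allclose(t1.sum_ed_s, t2.sum_ed_s)

    def test_stopping_table_file(self, tmp_path):
        path = tmp_path / "table.txt"
        path.write_text("# E_MeV S_el\n1 10\n10 20\n100 40\n")
        table = read_stopping_power(path, "proton")
        assert table.particle_kind == "proton"
        assert lookup_stopping_power(table, 10.0) == pytest.approx(20.0)
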