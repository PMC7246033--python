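"""Synthetic cohort generator: determinism, area contract, recovery."""

import math

import numpy as np
import pytest

import iphplc as ip
from iphplc.errors import ValidationError
from tests.conftest import HK

ABS = ("A", "B") + HK


def tiny_spec(**kw):
    defaults = dict(
        antibodies=ABS,
        timepoints_h=(24,),
        ground_truth_pct={("A", 24): 120.0, ("B", 24): 85.0},
        noise_sd_mAU=0.0,
        replicate_cv=0.0,
        run_cv=0.0,
        n_replicates=2,
        seed=9,
    )
    defaults.update(kw)
    return ip.SimulationSpec(**defaults)


class TestSimulateTrace:
    def test_deterministic_per_seed_and_identity(self):
        spec = tiny_spec(noise_sd_mAU=0.1, replicate_cv=0.03, run_cv=0.04)
        t1 = ip.simulate_trace(spec, "A", "treated", 24, 1)
        t2 = ip.simulate_trace(spec, "A", "treated", 24, 1)
        np.testing.assert_array_equal(t1.absorbance_mAU, t2.absorbance_mAU)
        t3 = ip.simulate_trace(spec, "A", "treated", 24, 2)
        assert not np.array_equal(t1.absorbance_mAU, t3.absorbance_mAU)

    def test_area_contract(self):
        # noise-free integral matches the target raw area within 0.1%
        spec = tiny_spec()
        wide = ip.PeakWindow(12.0 - 5 * 12 / 60, 12.0 + 5 * 12 / 60)
        tr = ip.simulate_trace(spec, "A", "control", 24, 1)
        corrected = ip.correct_baseline(tr, wide)
        area = ip.integrate_window(corrected, wide)
        target = spec.control_area_mAU_s * (1 + spec.negative_fraction)
        assert area == pytest.approx(target, rel=1e-3)

    def test_truth_symmetry_at_100(self):
        spec = tiny_spec(ground_truth_pct={})
        w = spec.default_window()
        at = ip.integrate_window(
            ip.correct_baseline(ip.simulate_trace(spec, "A", "treated", 24, 1), w), w
        )
        ac = ip.integrate_window(
            ip.correct_baseline(ip.simulate_trace(spec, "A", "control", 24, 1), w), w
        )
        assert at == pytest.approx(ac, rel=1e-3)

    def test_invalid_identity_rejected(self):
        spec = tiny_spec()
        with pytest.raises(ValidationError):
            ip.simulate_trace(spec, "nope", "treated", 24, 1)
        with pytest.raises(ValidationError):
            ip.simulate_trace(spec, "A", "treated", 36, 1)
        with pytest.raises(ValidationError):
            ip.simulate_trace(spec, "A", ip.ARM_NEGATIVE, None, 1)


class TestSimulateCohort:
    def test_counting_contract(self):
        spec = tiny_spec(n_replicates=3)
        sim = ip.simulate_cohort(spec)
        # 5 antibodies × 2 arms × 1 timepoint × 3 replicates + 3 negatives
        assert len(sim.traces) == 5 * 2 * 1 * 3 + 3
        assert len(sim.manifest) == len(sim.traces)
        assert len(sim.ground_truth) == 5

    def test_noise_free_recovery_exact(self):
        spec = tiny_spec()
        sim = ip.simulate_cohort(spec)
        _, levels = ip.quantify_cohort(sim.traces, spec.default_window())
        changes, _ = ip.analyze_levels(levels)
        by_ab = {c.antibody: c for c in changes}
        assert by_ab["A"].percent_level == pytest.approx(120.0, abs=0.2)
        assert by_ab["B"].percent_level == pytest.approx(85.0, abs=0.2)
        truth_bands = dict(
            zip(sim.ground_truth["antibody"], sim.ground_truth["true_band"])
        )
        for ab, c in by_ab.items():
            assert c.band == truth_bands[ab]

    def test_written_cohort_is_byte_deterministic(self, tmp_path):
        spec = tiny_spec(noise_sd_mAU=0.05, replicate_cv=0.02, run_cv=0.04)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        ip.simulate_cohort(spec, out_dir=d1)
        ip.simulate_cohort(spec, out_dir=d2)
        for p1 in sorted(d1.iterdir()):
            assert p1.read_bytes() == (d2 / p1.name).read_bytes()

    def test_written_cohort_round_trips_through_io(self, tmp_path):
        spec = tiny_spec()
        ip.simulate_cohort(spec, out_dir=tmp_path)
        traces = ip.read_cohort(tmp_path / "manifest.csv")
        _, levels = ip.quantify_cohort(traces, spec.default_window())
        changes, _ = ip.analyze_levels(levels)
        by_ab = {c.antibody: c for c in changes}
        assert by_ab["A"].percent_level == pytest.approx(120.0, abs=0.2)


class TestCalibratedNoise:
    def test_qc_pass_rate_with_default_noise(self):
        # 60 antibodies at the calibrated defaults: qc_pass ≥ 90%
        rng = np.random.default_rng(3)
        names = tuple(f"X{i}" for i in range(60)) + HK
        truth = {(n, 24): float(rng.uniform(70, 135)) for n in names[:60]}
        spec = ip.SimulationSpec(
            antibodies=names, timepoints_h=(24,), ground_truth_pct=truth, seed=13
        )
        sim = ip.simulate_cohort(spec)
        _, levels = ip.quantify_cohort(sim.traces, spec.default_window())
        changes, _ = ip.analyze_levels(levels)
        rate = np.mean([c.qc_pass for c in changes if c.antibody in names[:60]])
        assert rate >= 0.9


class TestSimulateCellCounts:
    def test_zero_dispersion_hits_target(self):
        records = ip.simulate_cell_counts("treated", 24, 73.1, dispersion_pct=0.0)
        for r in records:
            assert ip.proliferation_index(r.initial_count, r.final_count) == (
                pytest.approx(73.1, abs=100 / r.initial_count)
            )

    def test_reported_delta_recovered(self):
        treated = ip.simulate_cell_counts("treated", 24, 73.1, seed=1)
        control = ip.simulate_cell_counts("control", 24, 69.9, seed=1)
        d = ip.index_difference(
            ip.summarize_counts(treated, "treated", 24),
            ip.summarize_counts(control, "control", 24),
        )
        assert d == 3.2

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError):
            ip.simulate_cell_counts("treated", 24, 73.1, n_fields=0)
        with pytest.raises(ValidationError):
            ip.simulate_cell_counts("treated", 24, -101.0)
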