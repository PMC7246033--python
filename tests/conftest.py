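import numpy as np
import pytest

import iphplc as ip

HK = ("α-tubulin", "β-actin", "GAPDH")


def make_trace(time_min, absorbance, antibody="Ki-67", arm="treated",
               timepoint_h=24, replicate=1, sample_id="t"):
    return ip.ChromatogramTrace(
        sample_id=sample_id,
        antibody=antibody,
        arm=arm,
        timepoint_h=timepoint_h,
        replicate=replicate,
        time_min=np.asarray(time_min, dtype=float),
        absorbance_mAU=np.asarray(absorbance, dtype=float),
    )


def edge_safe_truths(rng, n, low=70.0, high=135.0, margin=0.5):
    """Uniform true percent levels avoiding the band-edge percents.

    Band edges on |Δ%| at 5/10/20 correspond to percent levels
    80, 90, 95, 105, 110, 120.
    """
    edges = (80.0, 90.0, 95.0, 105.0, 110.0, 120.0)
    out = []
    while len(out) < n:
        v = float(rng.uniform(low, high))
        if min(abs(v - e) for e in edges) > margin:
            out.append(v)
    return out


@pytest.fixture(scope="session")
def default_panel():
    return ip.load_default_panel()


@pytest.fixture(scope="session")
def small_noisy_cohort():
    """10 antibodies + housekeeping, 3 timepoints, default noise, analyzed."""
    rng = np.random.default_rng(2024)
    names = tuple(f"AB{i:02d}" for i in range(10)) + HK
    truth = {
        (n, tp): t
        for n in names[:10]
        for tp, t in zip((12, 24, 48), edge_safe_truths(rng, 3))
    }
    spec = ip.SimulationSpec(
        antibodies=names, ground_truth_pct=truth, seed=77
    )
    sim = ip.simulate_cohort(spec)
    _, levels = ip.quantify_cohort(sim.traces, spec.default_window())
    changes, reports = ip.analyze_levels(levels)
    return spec, sim, levels, changes, reports
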