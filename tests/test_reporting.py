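"""Report builders: group series, star/dot plot data, exports."""

import pytest

import iphplc as ip
from iphplc.panel import PanelError
from tests.conftest import HK


@pytest.fixture(scope="module")
def panel_changes(default_panel):
    """Noise-free full-panel changes at one timepoint, plus ground truth."""
    names = tuple(dict.fromkeys(default_panel.primary_names()))
    # deterministic spread of Δ over −29.75..+30.25, off the band boundaries
    truth = {
        (n, 24): 100.25 + ((i * 7) % 61 - 30)
        for i, n in enumerate(names)
        if n not in HK
    }
    spec = ip.SimulationSpec(
        antibodies=names,
        timepoints_h=(24,),
        ground_truth_pct=truth,
        noise_sd_mAU=0.0,
        replicate_cv=0.0,
        run_cv=0.0,
        n_replicates=2,
        seed=4,
    )
    sim = ip.simulate_cohort(spec)
    _, levels = ip.quantify_cohort(sim.traces, spec.default_window())
    changes, _ = ip.analyze_levels(levels, default_panel)
    return changes, truth


def test_group_series_counts_match_panel(panel_changes, default_panel):
    changes, _ = panel_changes
    ras = ip.build_group_series(changes, default_panel, "RAS signaling")
    assert len(ras.antibodies) == 22
    nfkb = ip.build_group_series(changes, default_panel, "NFkB signaling")
    assert len(nfkb.antibodies) == 18  # 12 primaries + 6 resolved overlaps


def test_group_series_unknown_category_rejected(panel_changes, default_panel):
    changes, _ = panel_changes
    with pytest.raises(PanelError):
        ip.build_group_series(changes, default_panel, "no such pathway")


def test_empty_changes_give_missing_series(default_panel):
    series = ip.build_group_series([], default_panel, "RAS signaling")
    assert all(
        v is None for d in series.deltas.values() for v in d.values()
    )


def test_star_plot_order_fixed_across_timepoints(panel_changes, default_panel):
    changes, _ = panel_changes
    star = ip.build_star_plot_data(changes, default_panel, "Growth factor", 24)
    names = [n for n, _ in star.points]
    series = ip.build_group_series(changes, default_panel, "Growth factor")
    assert names == list(series.antibodies)


def test_dot_plot_threshold_against_ground_truth(panel_changes):
    changes, truth = panel_changes
    dots = ip.build_dot_plot_data(changes, threshold_pct=20.0)
    plotted = {name for name, _, _ in dots}
    # noise-free: plotted set == antibodies whose true |Δ| > 20
    expected = {ab for (ab, _), pct in truth.items() if abs(pct - 100) > 20}
    assert plotted == expected
    # antibodies with mid-sized true changes (10 < |Δ| < 16) are excluded
    mid = {ab for (ab, _), pct in truth.items() if 10 < abs(pct - 100) < 16}
    assert mid and not (mid & plotted)


def test_builders_do_not_mutate_changes(panel_changes, default_panel):
    changes, _ = panel_changes
    snapshot = list(changes)
    ip.build_group_series(changes, default_panel, "RAS signaling")
    ip.build_dot_plot_data(changes)
    assert changes == snapshot


def test_every_series_antibody_exists_in_catalog(panel_changes, default_panel):
    changes, _ = panel_changes
    primaries = set(default_panel.primary_names())
    for category in default_panel.categories:
        series = ip.build_group_series(changes, default_panel, category)
        assert set(series.antibodies) <= primaries


def test_export_results_deterministic_csvs(panel_changes, default_panel, tmp_path):
    changes, _ = panel_changes
    p1 = ip.export_results(changes, default_panel, tmp_path / "a",
                           categories=["RAS signaling"], figures=True)
    p2 = ip.export_results(changes, default_panel, tmp_path / "b",
                           categories=["RAS signaling"], figures=False)
    assert p1["results"].read_bytes() == p2["results"].read_bytes()
    assert p1["group_series"].read_bytes() == p2["group_series"].read_bytes()
    assert p1["star:RAS signaling"].exists()
    # row count = antibodies × timepoints analyzed
    import pandas as pd

    df = pd.read_csv(p1["results"])
    assert len(df) == len({c.antibody for c in changes})


def test_export_empty_cohort_writes_headers_only(default_panel, tmp_path):
    paths = ip.export_results([], default_panel, tmp_path, figures=False)
    import pandas as pd

    df = pd.read_csv(paths["results"])
    assert df.empty and list(df.columns)[0] == "antibody"
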