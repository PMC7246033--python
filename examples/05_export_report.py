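"""Full-panel run with exports: results CSV, group-series CSV, figures.

Simulates the whole packaged panel at one timepoint (noise-free, arbitrary
ground truth), analyzes it, and writes the line graph + star plot for one
pathway and the >±10% dot plot into ./example_output/.
"""

import iphplc as ip

catalog = ip.load_default_panel()
hk = set(catalog.housekeeping_names())
names = tuple(dict.fromkeys(catalog.primary_names()))
truth = {
    (n, 24): 100.25 + ((i * 7) % 61 - 30)
    for i, n in enumerate(names)
    if n not in hk
}

spec = ip.SimulationSpec(
    antibodies=names, timepoints_h=(24,), ground_truth_pct=truth,
    noise_sd_mAU=0.0, replicate_cv=0.0, run_cv=0.0, n_replicates=2, seed=0,
)
sim = ip.simulate_cohort(spec)
_, levels = ip.quantify_cohort(sim.traces, spec.default_window())
changes, _ = ip.analyze_levels(levels, catalog)

paths = ip.export_results(
    changes, catalog, "example_output",
    threshold_pct=10.0, categories=["RAS signaling"],
)
high = ip.build_dot_plot_data(changes, threshold_pct=10.0)
print(f"antibody × timepoint results: {len(changes)}")
print(f"antibodies with |Δ%| > 10 at some timepoint: {len({a for a,_,_ in high})}")
for key, p in paths.items():
    print(f"  {key:<20s} -> {p}")
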