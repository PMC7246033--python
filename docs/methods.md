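# Methods

## The measurement model

In an IP-HPLC screen, each target protein is captured from a cell lysate on a
protein A/G agarose column loaded with one antibody, eluted, and detected by
UV absorbance at 280 nm (0.4 mL/min mobile phase, 30 min run). The whole
eluate appears as a single dominant elution peak; the quantity carried
forward is its area in mAU*s.

The chain from trace to expression level is:

1. **Baseline correction.** The straight line through the absorbance values
   at the integration-window endpoints is subtracted inside the window.
   This removes constant offsets and linear drift exactly and is isolated
   behind one function so a different local-baseline model can be swapped in;
   the model identifier is stamped into every `PeakAreaRecord`.
2. **Integration.** Trapezoidal rule on the native time grid, minutes
   converted to seconds first so areas are in mAU*s. No rectification: a
   noisy corrected trace may contribute small negative samples.
3. **Negative-control subtraction.** The peak area of an irrelevant
   (negative-control) antibody estimates nonspecific binding and is
   subtracted from every raw area. A result below zero is floored at 0 and
   flagged (`clamped`) rather than propagated into the square root.
4. **Square root.** The expression level is √(net area). Peak area grows
   roughly quadratically with captured protein in this assay, so the square
   root puts treated/control comparisons on a proportional scale. The
   method yields only *relative* levels; absolute concentrations are out of
   reach by construction.

Percent level per replicate is 100 × treated level / control level, pairing
treated and control runs of the same replicate index (the arms are run
sequentially on the instrument precisely to allow this pairing).

## Proportional basal-line (housekeeping) adjustment

Three housekeeping proteins (α-tubulin, β-actin, GAPDH) are assumed
expression-stable. Each replicate sample's percent levels are all multiplied
by one factor k = 100 / mean(housekeeping percent levels), setting the
housekeeping mean to exactly 100%. "Proportional" is read as multiplicative;
the mean of the three housekeeping proteins is the simplest symmetric
target. Whether each *individual* housekeeping protein then sits within ±5%
is verified and reported (`AdjustmentReport.within_tolerance`), never
forced. This single rescale is what removes run-level (loading/injection)
variation; it cannot remove per-antibody noise.

## Replicate statistics and change bands

Replicates (2–6; more than 6 computes with a warning) are aggregated as
mean, population SD, and SEM = √(σ²/n). The population variance (ddof = 0)
is the literal reading of s = √(σ²/n) with no correction term; it is
configurable (`variance_ddof`). QC passes when SD ≤ 5 percentage points —
the bench rule is to repeat runs until this holds, which software cannot do,
so failures are flagged in the output rather than dropped.

Δ% = mean percent level − 100 is classified by |Δ|:
minimal ≤ 5 < slight ≤ 10 < meaningful ≤ 20 < marked. The printed band
definitions overlap at the edges; boundary values are assigned to the lower
band (so |Δ| = 20 is meaningful, |Δ| > 20 is marked), a deterministic
convention configurable via `PipelineConfig.band_edges`.

## Panel catalog

The packaged panel transcribes the published 218-antibody, 20-category
table with 73 parenthetical overlap references (antibodies relevant to a
second pathway but measured once, under their primary category). Overlaps
resolve by exact normalized name — no fuzzy matching, for testability.
Several itemized parenthetical lists in the source table are internally
inconsistent with their printed counts; the reconciliations (spelling
normalizations, duplicate collapses, one promoted primary, four
reconstructed cross-references) are itemized in
`src/iphplc/data/panel218.CHANGELOG.md` and tagged `reconstructed` in
the fixture rather than silently merged.

## Proliferation index

Per image field, 100 × (final − initial count)/initial count; an arm's
index is the unweighted mean over its ten fields (a pooled-counts variant is
available via `pooled=True`), and the dispersion reported is the SD across
fields — the source's ± values are not labelled SD vs SEM, so ours is named
explicitly. Arm differences are reported to one decimal in percentage
points.

## Synthetic cohorts

The generator emulates what the pipeline consumes, with ground truth encoded
in the reported quantity: a treated peak's specific area is
control area × (R/100)², so √-of-area recovery of the true percent level R
is exact on noise-free data. Defaults (order-of-magnitude choices where the
assay's real dynamic range is unpublished, recorded here rather than
asserted as measured values):

| parameter | default | meaning |
|---|---|---|
| `control_area_mAU_s` | 600 | specific control peak area |
| `peak_center_min`, `peak_sd_s` | 12 min, 12 s | Gaussian elution peak |
| `negative_fraction` | 0.10 | nonspecific area as a fraction of control |
| `baseline_offset_mAU`, `baseline_slope_mAU_per_min` | 2, 0.05 | linear drift |
| `noise_sd_mAU` | 0.05 | additive white detector noise |
| `run_cv` | 0.04 | shared per-run lognormal area factor |
| `replicate_cv` | 0.015 | independent per-antibody lognormal factor |
| `n_replicates` | 4 | within the assay's 2–6 range |
| `sampling_step_s` | 1.0 | 1801 samples over 30 min |

Nonspecific binding co-elutes with the specific signal, so specific-arm
traces integrate to target + nonspecific and the negative-control channel
to nonspecific alone; the pipeline's subtraction then recovers the specific
target exactly. Replicate variability is multiplicative on true area and
split into a *shared per-run* factor — the loading/injection variation that
motivates the housekeeping adjustment, without which that pipeline stage
would be inert on synthetic data — and an *independent per-antibody*
factor. The split is calibrated so the raw replicate percent-level SD is
≈ 3 percentage points (inside the assay's ≤ ±5% repeat-until regime) while
the post-adjustment replicate mean recovers truth to within ±2 points for
the large majority of antibodies; at this noise the residual error budget
per antibody is roughly 0.6 points independent noise plus a ~0.3-point
cohort-wide residual from estimating the run factor off only three
housekeeping proteins.

Everything is deterministic per (seed, run identity): per-trace generators
are derived from the cohort seed and a CRC of the identity string, so a
cohort is byte-identical across re-runs and traces can be regenerated
individually.

`simulate_cell_counts` draws per-field indices around a target with chosen
dispersion and rounds final counts to integers (initial count 1000 by
default, so a 73.1% target is hit exactly at zero dispersion).

### What the generator does not emulate

Real chromatograms with retention-time shifts, tailing/fronting peak
shapes, co-eluting contaminant peaks, detector saturation, or antibody
cross-reactivity. Passing the recovery suites therefore demonstrates that
the *computational* chain is faithful (units, normalization, adjustment,
statistics, classification) under the stated noise model — not that the
assay itself is accurate on real lysates.

## Numerical choices and degenerate inputs

- Integration error for a Gaussian peak at 1 s sampling is far below 0.1%,
  and the residual discretization bias is shape-dependent only, so it
  cancels in treated/control ratios; the default window is ±4 peak SDs
  (window truncation, ~6 × 10⁻⁵, also cancels in ratios).
- A zero control level raises `UndefinedRatioError` (failed control IP)
  instead of producing infinities; non-finite Δ% is rejected at
  classification.
- Trace validation enforces a strictly increasing time grid inside a 0–30
  min run, equal series lengths ≥ 2, and finite absorbance.
- Trace files round-trip at 9 significant digits (≤ 1e-6 relative error);
  CSV exports are byte-deterministic for identical inputs.
- Problem sizes used by the test and acceptance suites — 50-antibody
  noise-free and 200-antibody noisy cohorts at one timepoint, 10-antibody
  three-timepoint cohorts elsewhere — are chosen so the full suite completes
  in seconds while keeping the statistical checks well-powered.

## Known limitations

Single-peak quantification only (no deconvolution or exponentially modified
Gaussian fits); fixed shared integration window rather than per-run peak
detection; the Fig-8-style "representative subset" star plot takes a
user-supplied subset list because no authoritative enumeration exists; no
hypothesis tests across antibodies are performed (none are defined for the
assay).
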