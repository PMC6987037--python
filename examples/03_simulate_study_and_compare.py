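"""Simulate a full 50-batch study and run the method comparison.

Generates the default six-strain study (plate, ddPCR live/total, flow
live/dead/total), quantifies every raw observation, and prints the
per-method CV summary plus the Bland-Altman agreement for the three
viability-focused method pairs.
"""

import tempfile

from probenum import PipelineConfig, StudyDesign, run_compare, run_simulate

cfg = PipelineConfig(design=StudyDesign(seed=42))
with tempfile.TemporaryDirectory() as tmp:
    table = run_simulate(cfg, tmp)
report = run_compare(cfg, table, outdir=None)

print("method consistency (mean +/- sd of per-batch CV%, all 50 batches):")
for s in report["cv_summaries"]:
    if s["stratum"] == "All":
        print(f"  {s['method']:<10} {s['mean_cv_pct']:5.1f} +/- {s['sd_cv_pct']:.1f}")

print("\npairwise agreement (Method 1 vs Method 2):")
focus = {("Plate", "PCR.live"), ("Plate", "Flow.live"), ("PCR.live", "Flow.live")}
for a in report["pair_agreements"]:
    if (a["method_x"], a["method_y"]) in focus:
        print(f"  {a['method_x']} vs {a['method_y']}: r = {a['pearson_r']:.3f}, "
              f"slope = {a['slope']:.3f}, mean rel diff = {a['mean_rel_diff_pct']:+.1f}%, "
              f"LOA = ({a['loa_low_pct']:.1f}%, {a['loa_high_pct']:.1f}%)")

print("\nPlate counts carry the largest replicate scatter, flow cytometry is "
      "intermediate and ddPCR the tightest; the negative Plate-vs-PCR.live mean "
      "relative difference reflects dead-cell template surviving the viability dye.")
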