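"""From colony counts across a serial dilution to CFU per gram.

Two dilution levels are plated in triplicate; plates outside the 25-250
countable window are discarded and the remainder pooled into a weighted
CFU/g estimate.
"""

from probenum import PlateSeriesRecord, cfu_per_g, select_countable

series = [
    PlateSeriesRecord("batch-A", dilution_level=1e-7, plated_volume=1.0,
                      colony_counts=(312, 298, 305)),          # overgrown
    PlateSeriesRecord("batch-A", dilution_level=1e-8, plated_volume=1.0,
                      colony_counts=(33, 28, 35)),             # countable
]

countable, diagnostic = select_countable(series)
kept = [c for r in countable for c in r.colony_counts]
print(f"countable plates: {kept} (diagnostic: {diagnostic or 'none'})")

est = cfu_per_g(countable)
print(f"CFU/g = {est.count_per_g:.3e} from {est.n_plates} plates")
print(f"per-plate values: {[f'{v:.2e}' for v in est.per_plate_cfu_per_g]}")
print("The batch estimate is the pooled weighted mean "
      "sum(colonies) / sum(volume x dilution) x suspension mL per gram; "
      "per-plate values feed the replicate-CV analysis downstream.")
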