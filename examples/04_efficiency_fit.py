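"""Assay efficiency from a gDNA dilution series.

A template preparation measured at fraction 1 is serially diluted down to
2.5% and each point re-measured; regressing measured copies on the
theoretical yield gives the assay efficiency (100 x slope, acceptable
window 90-105%) and the linearity R^2.
"""

from probenum import fit_efficiency

reference = 2_350.0  # copies/uL measured on the undiluted preparation
series = [
    (1.0, 2_350.0),
    (0.5, 1_190.0),
    (0.25, 601.0),
    (0.1, 243.0),
    (0.05, 119.0),
    (0.025, 60.5),
]

fit = fit_efficiency(series, reference=reference)
print(f"slope = {fit.slope:.4f}, intercept = {fit.intercept:.1f} copies")
print(f"efficiency = {fit.efficiency_pct:.2f}%  "
      f"({'within' if fit.within_limits else 'OUTSIDE'} the 90-105% window)")
print(f"R^2 = {fit.r_squared:.4f}")
print("Efficiency near 100% with R^2 > 0.99 indicates the DNA liberation and "
      "assay chemistry recover template proportionally across the dilution range.")
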