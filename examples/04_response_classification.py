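"""Diameter-based treatment-response classification.

Four longitudinal tumor-diameter series illustrate the rules: complete
response (lesion gone at any visit within 12 months), partial response
(>30% shrinkage at 12 months), stable disease, progressive disease
(≥20% growth).  CR/PR form the responder group.
"""

from mbdwi import DiameterSeries, classify_response

cases = [
    DiameterSeries("complete-response", 40.0, ((3.0, 20.0), (7.0, 0.0), (12.0, 0.0))),
    DiameterSeries("partial-response", 40.0, ((6.0, 32.0), (12.0, 25.0))),
    DiameterSeries("stable-disease", 40.0, ((6.0, 38.0), (12.0, 36.0))),
    DiameterSeries("progressive", 40.0, ((6.0, 44.0), (12.0, 48.0))),
]

for series in cases:
    label = classify_response(series)
    d12 = series.followups[-1][1]
    change = 100.0 * (d12 - series.baseline_mm) / series.baseline_mm
    print(f"{series.patient_id:>18}: {label.category} ({label.group}), "
          f"decided at {label.decided_at_months:g} mo, 12-mo change {change:+.0f}%")
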