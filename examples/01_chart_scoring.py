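"""Snellen/logMAR conversion with letter-by-letter scoring.

A clinical score like "6/12 -1" (the 6/12 line read with one miss) maps to
logMAR log10(12/6) + 0.02 = 0.321; each optotype on a five-letter row is
worth 0.02 logMAR. The inverse mapping recovers the nearest chart line and
adjustment for reporting.
"""

from autova import ChartSpec, logmar_to_snellen, snellen_to_logmar

chart = ChartSpec.default()

for denom, adj in [(6, 0), (60, 0), (12, -1), (9, +2)]:
    lm = snellen_to_logmar(denom, adj)
    label = f"6/{denom} {adj:+d}" if adj else f"6/{denom}"
    print(f"{label:>9s}  ->  logMAR {lm:+.4f}")

line, adj = logmar_to_snellen(0.1561, chart)
print(f"\nlogMAR 0.1561 -> nearest chart score {line.snellen} {adj:+d}")
print("(one letter better than the 6/9 line: 0.1761 - 0.02)")
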