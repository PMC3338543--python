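"""Linear gradient geometry: the quartile split into steep and shallow ramps.

A patterned protein profile rises linearly over ~592 um.  Splitting it at
the first quartile gives a steep ramp (148 um span) and a shallow ramp
(444 um span) of equal peak concentration, so the steep slope is exactly
three times the shallow one.
"""

from neuriteguide import make_gradient_pair

high, low = make_gradient_pair(total_span_um=592.0, max_level=1.0)

print(f"steep ramp : span {high.span_um:6.1f} um, slope {high.slope:.6f} /um")
print(f"shallow ramp: span {low.span_um:6.1f} um, slope {low.slope:.6f} /um")
print(f"slope ratio steep/shallow: {high.slope / low.slope:.1f}")
print()
print("Concentration along the shallow ramp (0 = low end):")
for d in (0.0, 111.0, 222.0, 333.0, 444.0):
    print(f"  offset {d:5.1f} um -> {low.concentration(d):.3f} of peak")
print()
print("The ratio of 3 means a cell on the steep ramp sees a concentration")
print("difference across its body three times larger than on the shallow ramp.")
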