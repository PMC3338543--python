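"""How the user-set restriction angle drives the apparent guidance call.

The attracted and repulsed sectors have width R (default 120 deg).  This
sweep varies R from 60 to 180 for an unbiased and a biased population:
the unbiased ratio stays near 1 at every R, while the biased ratio is
largest for narrow sectors — the reason R must be reported alongside any
guidance claim.
"""

import numpy as np

from neuriteguide import restriction_sweep

rng = np.random.default_rng(1)
for kappa, label in ((0.0, "unbiased control"), (1.0, "biased, kappa=1")):
    angles = np.degrees(rng.vonmises(np.pi, kappa, 5000))
    sweep = restriction_sweep(angles, (60.0, 90.0, 120.0, 150.0, 180.0))
    print(f"{label} (n=5000):")
    print(
        sweep[["restriction_deg", "n_attracted", "n_neutral", "n_repulsed", "ratio", "p_value"]]
        .to_string(index=False, float_format=lambda v: f"{v:.4f}")
    )
    print()

print("Narrow sectors isolate the most strongly oriented neurites, inflating")
print("the attracted/repulsed ratio for a biased population.")
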