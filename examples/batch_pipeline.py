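"""End-to-end batch run: synthetic scenes to per-cell and summary tables.

Runs the whole pipeline on a small biased synthetic population and writes
the same outputs a run over a directory of micrographs would produce:
cells.csv, summary.csv, sweep.csv, accounting.csv and a manifest carrying
the frozen configuration and its hash.
"""

import tempfile
from pathlib import Path

from neuriteguide import RunConfig, run_synthetic, write_outputs

config = RunConfig(rng_seed=11)
result, scenes = run_synthetic(config, n_cells=24, bias_kappa=2.0)

print("accounting per frame:")
print(result.accounting.to_string(index=False))
print()
print("guidance summary at R = 120:")
cols = ["condition", "basis", "n_attracted", "n_neutral", "n_repulsed", "p_value"]
print(result.summary[cols].to_string(index=False, float_format=lambda v: f"{v:.4f}"))

out_dir = Path(tempfile.mkdtemp(prefix="neuriteguide_"))
paths = write_outputs(result, out_dir)
print()
print(f"tables written to {out_dir} (config hash {config.config_hash})")
print("With kappa=2 most neurites initiate toward the high-concentration edge,")
print("so attracted counts exceed repulsed on every angle basis.")
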