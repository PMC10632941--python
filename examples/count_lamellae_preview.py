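"""Produce the binary preview an operator counts lamellae on.

Before measurement the operator must tell the script how many bright and
dark lamellae the measurement area contains; this preview (preprocess +
binarization only) is what they count them on.
"""

import tempfile
from pathlib import Path

import lamellometry as lm
from lamellometry.pipeline import COUNTING_REMINDER

out = Path(tempfile.mkdtemp(prefix="lamellometry_"))
tif, _ = lm.write_fixture(lm.FixtureSpec(rotation_deg=-5.0, seed=3), out / "sample")

preview = lm.count_assist(lm.RunConfig(filepath=tif, output_dir=str(out)))

runs = lm.run_length_encode(preview)
n_runs = len(runs.columns[preview.pixels.shape[1] // 2])
print(f"preview written to {out / 'count_preview.png'}")
print(f"the central column crosses {n_runs} bands")
print(COUNTING_REMINDER)
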