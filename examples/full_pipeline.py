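"""One-call pipeline: simulate -> association scans -> PRS -> power.

Runs every stage from a single seeded configuration into a temporary
directory and prints the consolidated report. The same run is available
from the shell as `centscan run-all --out <dir> --seed 7`.
"""

import tempfile

from centscan import RunConfig, render_report, run_all

with tempfile.TemporaryDirectory() as tmp:
    config = RunConfig(
        out_dir=tmp, seed=7, panel_snps=86,
        simulate={"n_cases": 1000, "n_controls": 1000, "n_centenarians": 300},
    )
    manifest = run_all(config)
    print(render_report(manifest))
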