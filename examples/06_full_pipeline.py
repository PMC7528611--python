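"""Run the whole pipeline — simulate, detect, classify, report — in one call.

Equivalent to `circuitclock run-all --protocol acute --n-cells 20 --seed 5
--out scratch/demo`; prints the ground-truth recovery report.
"""

import json
import tempfile

from circuitclock import PipelineConfig, run_pipeline

config = PipelineConfig(seed=5, protocol="acute", n_cells=20)
with tempfile.TemporaryDirectory() as out:
    report = run_pipeline(config, out)

print(f"exact class recovery: {report['class_exact_recovery']:.2f}")
print("confusion (true class -> called class):")
print(json.dumps(report["class_confusion"], indent=1))
print("All stage tables (responses, classes, session files) were written to "
      "the output directory; identical config+seed reproduces them byte for byte.")
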