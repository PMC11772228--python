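"""One call from simulation to report.

Writes exposure.csv, scores.csv, results.json and report.md to out/,
fully deterministic under the seed.
"""

import nicugaze as ng
from nicugaze.pipeline import PipelineConfig

cfg = PipelineConfig(simulation=ng.SimulationConfig(seed=7), seed=7)
results = ng.run_pipeline(cfg, out_dir="out")

print(open("out/report.md").read())
print("The same run from a shell: "
      "`nicugaze run --seed 7 --out-dir out`")
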