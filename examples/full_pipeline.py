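"""Run the complete simulate -> analyze -> fit pipeline.

Writes trials.csv, regression.csv, ANOVA tables, per-subject fits and a
plain-text report (all stamped with the config hash and seed) into
./pipeline_demo, then prints the report.  Equivalent shell command:

    riskmotor run -o pipeline_demo
"""

import riskmotor as rm

config = rm.default_config()
bundle = rm.run_pipeline(config, output_dir="pipeline_demo")
print(bundle.paths["report"].read_text())
print("files written:", ", ".join(p.name for p in bundle.paths.values()))
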