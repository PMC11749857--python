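"""Run the full staged pipeline (simulate -> GLM -> selection -> meta ->
empirical) from one seed and inspect the machine-readable summary.

Equivalent shell command:
    python -m litbayes run --seed 11 --outdir scratch/pipeline_run \
        --chains 4 --iterations 1500 --warmup 500 --n-patients 1200
"""

import json

from litbayes.pipeline import RunConfig, run_pipeline

config = RunConfig(seed=11, outdir="scratch/pipeline_run", n_patients=1200,
                   chains=4, iterations=1500, warmup=500, folds=3, max_size=4)
summary = run_pipeline(config)

print("stages:", [k for k in summary if k not in ("config", "diagnostics_ok")])
print("all diagnostics passed:", summary["diagnostics_ok"])
print("selection ranking:", summary["select"]["ranking"][:4], "...")
print(f"meta exp(mu): {summary['meta']['exp_mu_mean']:.2f} "
      f"({summary['meta']['exp_mu_2.5']:.2f}-{summary['meta']['exp_mu_97.5']:.2f})")
print(json.dumps(summary["glm"], indent=2))

# Every artifact under the output directory (tables, posterior summaries,
# selection path, forest-plot data, run log) is reproducible from the
# (config, seed) pair alone.
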