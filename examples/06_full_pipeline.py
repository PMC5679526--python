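"""Run the full pipeline end to end on synthetic data.

Stages: generate/load expression + target tables -> differential
expression filter (|fc| >= 2, BH p <= 0.05) -> closed-loop inference ->
distance-correlation edge screening -> per-loop mediation with bootstrap
-> classification -> motif detection. Every output TSV lands in the run
directory together with a reproducibility manifest.
"""

import tempfile
from pathlib import Path

import yaml

from loopmed import PipelineConfig, run_pipeline
from loopmed.pipeline import SyntheticBlock

config = PipelineConfig(
    seed=1,
    n_boot=500,
    n_random_graphs=100,
    motif_sizes=[3],
    synthetic=SyntheticBlock(
        n_triads_per_class={"M_T": 6, "M_M": 6, "M_TM": 6, "NULL": 6},
        n_decoy_edges=12,
        n_samples=60,
        noise_sd=0.5,
    ),
)
out = run_pipeline(config, Path(tempfile.mkdtemp()) / "run")
summary = yaml.safe_load((out / "summary.yaml").read_text())

print("run directory:", out)
print("loops inferred:", summary["n_loops_inferred"],
      "| screened:", summary["n_loops_screened"])
print("class counts:", summary["class_counts"])
print(f"explained fraction: {summary['explained_fraction']:.0%}")
print("files:", sorted(p.name for p in out.glob("*.tsv"))[:6], "...")
# Rerunning with the same config reproduces every TSV byte for byte.
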