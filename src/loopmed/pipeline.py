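"""End-to-end pipeline: data -> DE filter -> loops -> screening ->
mediation -> classification -> motif detection.

Each run writes per-stage TSVs, a YAML summary with the class counts, and
a reproducibility manifest (config hash, seed, library versions). All
randomness derives from the single config seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import (
    class_counts,
    classification_frame,
    classify,
    direction_tables,
    subclassify_mtm,
    top_effects,
)
from . import loops as loops_mod
from . import motifs as motifs_mod
from . import preprocess, screening, synthetic
from .mediation import mediate

logger = logging.getLogger(__name__)


@dataclass
class SyntheticBlock:
    n_triads_per_class: dict = field(
        default_factory=lambda: {"M_T": 10, "M_M": 10, "M_TM": 10, "NULL": 10}
    )
    n_decoy_edges: int = 20
    n_samples: int = 50
    noise_sd: float = 0.5
    fc_magnitude: float = 2.5


@dataclass
class PipelineConfig:
    """Validated configuration; defaults are the analysis' stated settings
    (alpha 0.05, absolute fold change 2, 1000 bootstrap draws, 1000 null
    graphs)."""

    seed: int = 0
    alpha: float = 0.05
    fc_threshold: float = 2.0
    n_boot: int = 1000
    n_random_graphs: int = 1000
    motif_sizes: list = field(default_factory=lambda: [3, 4])
    orientation: str = "miRNA_treats_TF_mediates"
    time_point: str = "24h"
    normalize: bool = False
    input_dir: str | None = None
    synthetic: SyntheticBlock = field(default_factory=SyntheticBlock)


_RANGES = {
    "alpha": (0.0, 1.0),
    "fc_threshold": (1.0, float("inf")),
    "n_boot": (100, float("inf")),
    "n_random_graphs": (1, float("inf")),
}


def validate_config(raw: dict | str | Path | None) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file or dict.

    Unknown keys are rejected; all range violations are reported together
    in one error.
    """
    if raw is None:
        raw = {}
    if isinstance(raw, (str, Path)):
        loaded = yaml.safe_load(Path(raw).read_text())
        raw = loaded if loaded is not None else {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")

    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    errors = [f"unknown config key: {k!r}" for k in raw if k not in known]
    cfg_kwargs = {k: v for k, v in raw.items() if k in known}
    if "synthetic" in cfg_kwargs:
        syn_known = {f.name for f in dataclasses.fields(SyntheticBlock)}
        syn_raw = cfg_kwargs["synthetic"] or {}
        errors += [
            f"unknown synthetic key: {k!r}" for k in syn_raw if k not in syn_known
        ]
        cfg_kwargs["synthetic"] = SyntheticBlock(
            **{k: v for k, v in syn_raw.items() if k in syn_known}
        )
    cfg = PipelineConfig(**cfg_kwargs)
    for key, (lo, hi) in _RANGES.items():
        v = getattr(cfg, key)
        if not (lo <= v <= hi):
            errors.append(f"{key}={v} outside [{lo}, {hi}]")
    if cfg.orientation not in (
        "miRNA_treats_TF_mediates",
        "TF_treats_miRNA_mediates",
    ):
        errors.append(f"unknown orientation {cfg.orientation!r}")
    if any(k not in (3, 4, 5) for k in cfg.motif_sizes):
        errors.append("motif_sizes must be within {3, 4, 5} for exact enumeration")
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    return cfg


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute all stages, writing TSVs + summary + manifest to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        # Step I: data + differential expression
        stage = "data"
        if config.input_dir:
            ds = synthetic.read_dataset(config.input_dir)
        else:
            s = config.synthetic
            ds = synthetic.generate_dataset(
                n_triads_per_class=s.n_triads_per_class,
                n_decoy_edges=s.n_decoy_edges,
                n_samples=s.n_samples,
                noise_sd=s.noise_sd,
                fc_magnitude=s.fc_magnitude,
                seed=config.seed,
                time_point=config.time_point,
            )
            synthetic.write_dataset(ds, out / "dataset")
        matrices = {
            "mirna": ds.mirna_expr,
            "tf": ds.tf_expr,
            "gene": ds.gene_expr,
        }
        if config.normalize:
            matrices = {k: preprocess.normalize(m) for k, m in matrices.items()}

        stage = "differential_expression"
        universe: dict[str, set] = {}
        fc: dict[str, dict[str, float]] = {}
        for kind, matrix in matrices.items():
            records = preprocess.differential_expression(
                matrix,
                config.time_point,
                fc_threshold=config.fc_threshold,
                alpha=config.alpha,
            )
            preprocess.de_frame(records).to_csv(
                out / f"de_{kind}.tsv", sep="\t", index=False
            )
            universe[kind] = {r.entity_id for r in records if r.passes}
            fc[kind] = {r.entity_id: r.fc for r in records}
        logger.info(
            "DE pass counts: %s", {k: len(v) for k, v in universe.items()}
        )

        # Step II: loop inference
        stage = "loop_inference"
        loops = loops_mod.infer_closed_loops(
            ds.mirna_targets, ds.tf_targets, universe
        )
        loops_mod.write_loops(loops, out / "loops.tsv")
        logger.info("inferred %d closed loops", len(loops))

        # Step III: screening + mediation on injured-condition samples
        stage = "screening"
        inj = {
            k: m.subset_samples(condition="injured", time_point=config.time_point)
            for k, m in matrices.items()
        }
        screened = screening.screen_loops(
            loops, inj["mirna"], inj["tf"], inj["gene"], alpha=config.alpha
        )
        screening.screened_frame(screened).to_csv(
            out / "screened.tsv", sep="\t", index=False
        )
        logger.info("%d loops pass edge screening", len(screened))

        stage = "mediation"
        base = np.random.default_rng(config.seed)
        loop_seeds = base.integers(2**31, size=max(len(screened), 1))
        results = []
        reversed_orientation = config.orientation == "TF_treats_miRNA_mediates"
        for sl, lseed in zip(screened, loop_seeds):
            x = inj["mirna"].row(sl.loop.mirna_id)
            m = inj["tf"].row(sl.loop.tf_id)
            if reversed_orientation:
                x, m = m, x
            y = inj["gene"].row(sl.loop.gene_id)
            results.append(
                mediate(
                    x,
                    m,
                    y,
                    kind_m=sl.kind_m,
                    kind_y=sl.kind_y,
                    n_boot=config.n_boot,
                    seed=int(lseed),
                    orientation=config.orientation,
                    loop=sl.loop,
                )
            )
        mediation_frame(results).to_csv(out / "mediation.tsv", sep="\t", index=False)

        # Step IV: classification + motifs
        stage = "classification"
        classified = []
        for r in results:
            c = classify(
                r,
                alpha=config.alpha,
                fc_mirna=fc["mirna"].get(r.loop.mirna_id, float("nan")),
                fc_tf=fc["tf"].get(r.loop.tf_id, float("nan")),
                fc_gene=fc["gene"].get(r.loop.gene_id, float("nan")),
            )
            if c.cls == "M_TM":
                c = subclassify_mtm(c)
            classified.append(c)
        classification_frame(classified).to_csv(
            out / "classification.tsv", sep="\t", index=False
        )
        counts = class_counts(classified)
        counts.to_csv(out / "class_counts.tsv", sep="\t", index=False)
        for name, tbl in direction_tables(classified).items():
            tbl.to_csv(out / f"direction_{name}.tsv", sep="\t", index=False)
        top_effects(results, classified).to_csv(
            out / "top_effects.tsv", sep="\t", index=False
        )

        stage = "motifs"
        explained = [c.loop for c in classified if c.cls != "UNEXPLAINED"]
        graph = loops_mod.loops_to_graph(explained)
        loops_mod.write_graph_edgelist(graph, out / "mediated_graph.tsv")
        for k in config.motif_sizes:
            records = motifs_mod.motif_significance(
                graph,
                k,
                n_random=config.n_random_graphs,
                seed=int(base.integers(2**31)),
            )
            motifs_mod.motif_frame(records).to_csv(
                out / f"motifs_k{k}.tsv", sep="\t", index=False
            )
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    summary = {
        "n_loops_inferred": len(loops),
        "n_loops_screened": len(screened),
        "class_counts": {
            c: int(counts[c].iloc[0]) for c in ("M_T", "M_M", "M_TM", "UNEXPLAINED")
        },
        "explained_fraction": float(counts["explained_fraction"].iloc[0])
        if len(results)
        else None,
    }
    (out / "summary.yaml").write_text(yaml.safe_dump(summary, sort_keys=False))
    versions = {}
    for mod in ("numpy", "scipy", "pandas", "networkx", "statsmodels"):
        versions[mod] = __import__(mod).__version__
    manifest = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "config_hash": _config_hash(config),
        "versions": versions,
    }
    (out / "manifest.yaml").write_text(
        yaml.safe_dump(manifest, sort_keys=False, default_flow_style=False)
    )
    return out


def mediation_frame(results) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "mirna_id": r.loop.mirna_id if r.loop else "",
                "tf_id": r.loop.tf_id if r.loop else "",
                "gene_id": r.loop.gene_id if r.loop else "",
                "orientation": r.orientation,
                "acme": r.acme,
                "ade": r.ade,
                "te": r.te,
                "acme_ci_lo": r.acme_ci[0],
                "acme_ci_hi": r.acme_ci[1],
                "ade_ci_lo": r.ade_ci[0],
                "ade_ci_hi": r.ade_ci[1],
                "acme_p": r.acme_p,
                "ade_p": r.ade_p,
                "te_p": r.te_p,
                "sobel_se": r.sobel_se,
                "model_m_kind": r.model_m_kind,
                "model_y_kind": r.model_y_kind,
                "n_boot": r.n_boot,
                "seed": r.seed,
            }
        )
    return pd.DataFrame(rows)
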