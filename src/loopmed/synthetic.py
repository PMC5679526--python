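"""Synthetic expression data with planted mediation structure.

Generates miRNA/TF/gene expression matrices and regulator->target tables
in which a known set of closed triads (miRNA -> TF -> gene) carries
planted structural coefficients, so that loop inference, screening,
mediation and classification can all be validated against exact truth.

For each triad the injured-condition samples satisfy the mediation
structural equations exactly:

    X = baseline_x + x_sig,              x_sig ~ N(0, 1)
    M = beta2 + a X + N(0, noise_sd_m)
    Y = beta3 + c' X + b M + N(0, noise_sd_y)

Intended classes fix the coefficient pattern: M_T (TF-mediated) has
a, b != 0 and c' = 0; M_M (miRNA-only) has a != 0, b = 0, c' != 0 (so all
three edges stay correlated while nothing is routed through the TF);
M_TM has all three nonzero; NULL has none. Injured-vs-sham fold changes
of at least ``fc_magnitude`` are planted multiplicatively on the
baselines of every loop member (direction random per entity) and are ~1
for decoys, so the planted loops survive a |fc| >= 2 differential-
expression filter while decoys do not. Decoy edges are rejection-sampled
so they never close an unplanned triad: the planted truth is the exact
loop set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .expression import ExpressionMatrix
from .loops import CandidateLoop, TargetTable

CLASSES = ("M_T", "M_M", "M_TM", "NULL")

DEFAULT_COEFF_RANGES = {"a": (0.75, 1.25), "b": (0.75, 1.25), "c_prime": (0.75, 1.25)}


@dataclass(frozen=True)
class TriadSpec:
    """Ground truth for one planted triad."""

    mirna_id: str
    tf_id: str
    gene_id: str
    a: float
    b: float
    c_prime: float
    noise_sd_m: float
    noise_sd_y: float
    intended_class: str

    def __post_init__(self) -> None:
        cls = self.intended_class
        if cls not in CLASSES:
            raise ValueError(f"unknown class {cls!r}")
        a, b, cp = self.a, self.b, self.c_prime
        ok = {
            "M_T": a != 0 and b != 0 and cp == 0,
            "M_M": cp != 0 and a * b == 0,
            "M_TM": a != 0 and b != 0 and cp != 0,
            "NULL": a == 0 and b == 0 and cp == 0,
        }[cls]
        if not ok:
            raise ValueError(
                f"coefficients (a={a}, b={b}, c'={cp}) violate class {cls}"
            )
        if self.noise_sd_m < 0 or self.noise_sd_y < 0:
            raise ValueError("noise standard deviations must be >= 0")

    @property
    def loop(self) -> CandidateLoop:
        return CandidateLoop(self.mirna_id, self.tf_id, self.gene_id)


@dataclass
class SyntheticDataset:
    mirna_expr: ExpressionMatrix
    tf_expr: ExpressionMatrix
    gene_expr: ExpressionMatrix
    mirna_targets: TargetTable
    tf_targets: TargetTable
    truth: list[TriadSpec]
    seed: int
    time_point: str = "24h"

    def truth_loops(self) -> list[CandidateLoop]:
        return sorted(t.loop for t in self.truth)

    def equals(self, other: "SyntheticDataset") -> bool:
        return (
            self.mirna_expr.equals(other.mirna_expr)
            and self.tf_expr.equals(other.tf_expr)
            and self.gene_expr.equals(other.gene_expr)
            and self.mirna_targets.records.equals(other.mirna_targets.records)
            and self.tf_targets.records.equals(other.tf_targets.records)
            and self.truth == other.truth
            and self.seed == other.seed
        )


def _draw_coeff(rng: np.random.Generator, rng_pair, random_signs: bool) -> float:
    lo, hi = rng_pair
    if lo <= 0 <= hi and (lo, hi) != (0.0, 0.0):
        raise ValueError(f"coefficient range {rng_pair} must exclude 0")
    val = rng.uniform(lo, hi)
    if random_signs and rng.random() < 0.5:
        val = -val
    return float(val)


def generate_dataset(
    n_triads_per_class: dict[str, int],
    n_decoy_edges: int = 0,
    n_samples: int = 20,
    coeff_ranges: dict[str, tuple[float, float]] | None = None,
    noise_sd: float = 0.5,
    fc_magnitude: float = 2.5,
    seed: int = 0,
    n_sham: int | None = None,
    random_signs: bool = True,
    time_point: str = "24h",
) -> SyntheticDataset:
    """Generate a dataset with planted triads, fold changes and decoys.

    Parameters
    ----------
    n_triads_per_class
        e.g. ``{"M_T": 10, "NULL": 5}``; classes absent default to 0.
    n_decoy_edges
        Extra random target-table edges that never close a triad.
    n_samples
        Injured-condition sample count (the correlation sample size);
        must be >= 10 for the dcor t-test approximation downstream.
    coeff_ranges
        Magnitude interval per coefficient (a, b, c_prime); a random sign
        is applied per triad unless ``random_signs`` is False.
    noise_sd
        Gaussian noise s.d. of the mediator and outcome equations.
    fc_magnitude
        Planted injured/sham fold-change magnitude for loop members
        (must be >= 2 so members pass the default DE filter).
    """
    if n_samples < 10:
        raise ValueError("n_samples must be >= 10 (dcor t-test approximation)")
    if n_samples == 0:
        raise ValueError("zero samples")
    counts = {c: int(n_triads_per_class.get(c, 0)) for c in CLASSES}
    if any(v < 0 for v in counts.values()):
        raise ValueError("class counts must be >= 0")
    if sum(counts.values()) == 0:
        raise ValueError("at least one triad class count must be positive")
    if fc_magnitude < 2:
        raise ValueError("fc_magnitude must be >= 2")
    ranges = dict(DEFAULT_COEFF_RANGES)
    if coeff_ranges:
        ranges.update(coeff_ranges)
    n_sham = n_samples if n_sham is None else n_sham
    if n_sham < 2:
        raise ValueError("need >= 2 sham samples for the DE filter")

    rng = np.random.default_rng(np.random.SeedSequence(seed))

    # --- triad specs -------------------------------------------------------
    truth: list[TriadSpec] = []
    i = 0
    for cls in CLASSES:
        for _ in range(counts[cls]):
            i += 1
            a = b = cp = 0.0
            if cls in ("M_T", "M_TM"):
                a = _draw_coeff(rng, ranges["a"], random_signs)
                b = _draw_coeff(rng, ranges["b"], random_signs)
            if cls == "M_M":
                a = _draw_coeff(rng, ranges["a"], random_signs)
            if cls in ("M_M", "M_TM"):
                cp = _draw_coeff(rng, ranges["c_prime"], random_signs)
            truth.append(
                TriadSpec(
                    mirna_id=f"miR-{i:04d}",
                    tf_id=f"TF-{i:04d}",
                    gene_id=f"G-{i:04d}",
                    a=a,
                    b=b,
                    c_prime=cp,
                    noise_sd_m=noise_sd,
                    noise_sd_y=noise_sd,
                    intended_class=cls,
                )
            )

    # --- samples -----------------------------------------------------------
    inj_ids = [f"inj{j:03d}" for j in range(1, n_samples + 1)]
    sham_ids = [f"sham{j:03d}" for j in range(1, n_sham + 1)]
    meta = pd.DataFrame(
        {
            "time_point": [time_point] * (n_samples + n_sham),
            "condition": ["injured"] * n_samples + ["sham"] * n_sham,
            "replicate": list(range(1, n_samples + 1)) + list(range(1, n_sham + 1)),
        },
        index=pd.Index(inj_ids + sham_ids, name="sample_id"),
    )

    def baselines(entity_rng, member: bool):
        base = entity_rng.uniform(8.0, 12.0)
        if not member:
            return base, base
        factor = fc_magnitude if entity_rng.random() < 0.5 else 1.0 / fc_magnitude
        return base * factor, base  # injured, sham

    mirna_rows, tf_rows, gene_rows = {}, {}, {}
    for spec in truth:
        bx_i, bx_s = baselines(rng, member=True)
        bm_i, bm_s = baselines(rng, member=True)
        by_i, by_s = baselines(rng, member=True)
        for (bx, bm, by), nn, store in (
            ((bx_i, bm_i, by_i), n_samples, "inj"),
            ((bx_s, bm_s, by_s), n_sham, "sham"),
        ):
            x_sig = rng.standard_normal(nn)
            e2 = rng.standard_normal(nn) * spec.noise_sd_m
            e3 = rng.standard_normal(nn) * spec.noise_sd_y
            m_sig = spec.a * x_sig + e2
            y_sig = spec.c_prime * x_sig + spec.b * m_sig + e3
            if store == "inj":
                xi, mi, yi = bx + x_sig, bm + m_sig, by + y_sig
            else:
                xs, ms, ys = bx + x_sig, bm + m_sig, by + y_sig
        mirna_rows[spec.mirna_id] = np.concatenate([xi, xs])
        tf_rows[spec.tf_id] = np.concatenate([mi, ms])
        gene_rows[spec.gene_id] = np.concatenate([yi, ys])

    # --- target tables with planted edges ----------------------------------
    mirna_edges = {(t.mirna_id, t.tf_id, "TF") for t in truth} | {
        (t.mirna_id, t.gene_id, "gene") for t in truth
    }
    tf_edges = {(t.tf_id, t.gene_id) for t in truth}

    # decoy entities (independent noise, fold change ~ 1)
    n_decoy_entities = max(2, int(np.ceil(n_decoy_edges / 2))) if n_decoy_edges else 0
    decoy_mirnas = [f"miR-d{j:03d}" for j in range(1, n_decoy_entities + 1)]
    decoy_tfs = [f"TF-d{j:03d}" for j in range(1, n_decoy_entities + 1)]
    decoy_genes = [f"G-d{j:03d}" for j in range(1, n_decoy_entities + 1)]
    for ident, store in (
        (decoy_mirnas, mirna_rows),
        (decoy_tfs, tf_rows),
        (decoy_genes, gene_rows),
    ):
        for eid in ident:
            base = rng.uniform(8.0, 12.0)
            store[eid] = base + rng.standard_normal(n_samples + n_sham)

    all_mirnas = sorted(mirna_rows)
    all_tfs = sorted(tf_rows)
    all_genes = sorted(gene_rows)

    def would_close_triad(kind, u, v, me, te):
        if kind == "mi_tf":
            return any((u, g, "gene") in me and (v, g) in te for g in all_genes)
        if kind == "mi_gene":
            return any((u, tf, "TF") in me and (tf, v) in te for tf in all_tfs)
        return any((mi, u, "TF") in me and (mi, v, "gene") in me for mi in all_mirnas)

    placed, attempts = 0, 0
    while placed < n_decoy_edges and attempts < 200 * max(n_decoy_edges, 1):
        attempts += 1
        kind = ("mi_tf", "mi_gene", "tf_gene")[rng.integers(0, 3)]
        if kind == "mi_tf":
            u = all_mirnas[rng.integers(len(all_mirnas))]
            v = all_tfs[rng.integers(len(all_tfs))]
            if (u, v, "TF") in mirna_edges or would_close_triad(kind, u, v, mirna_edges, tf_edges):
                continue
            mirna_edges.add((u, v, "TF"))
        elif kind == "mi_gene":
            u = all_mirnas[rng.integers(len(all_mirnas))]
            v = all_genes[rng.integers(len(all_genes))]
            if (u, v, "gene") in mirna_edges or would_close_triad(kind, u, v, mirna_edges, tf_edges):
                continue
            mirna_edges.add((u, v, "gene"))
        else:
            u = all_tfs[rng.integers(len(all_tfs))]
            v = all_genes[rng.integers(len(all_genes))]
            if (u, v) in tf_edges or would_close_triad(kind, u, v, mirna_edges, tf_edges):
                continue
            tf_edges.add((u, v))
        placed += 1
    if placed < n_decoy_edges:
        raise RuntimeError(
            f"could only place {placed}/{n_decoy_edges} decoy edges without closing triads"
        )

    mirna_table = TargetTable(
        pd.DataFrame(
            [(mi, "miRNA", tgt, kind, "synthetic", np.nan) for mi, tgt, kind in sorted(mirna_edges)],
            columns=["regulator_id", "regulator_kind", "target_id", "target_kind", "source", "score"],
        )
    )
    tf_table = TargetTable(
        pd.DataFrame(
            [(tf, "TF", g, "gene", "synthetic", np.nan) for tf, g in sorted(tf_edges)],
            columns=["regulator_id", "regulator_kind", "target_id", "target_kind", "source", "score"],
        )
    )

    def matrix(rows: dict[str, np.ndarray]) -> ExpressionMatrix:
        df = pd.DataFrame.from_dict(rows, orient="index", columns=meta.index)
        return ExpressionMatrix(df.sort_index(), meta)

    return SyntheticDataset(
        mirna_expr=matrix(mirna_rows),
        tf_expr=matrix(tf_rows),
        gene_expr=matrix(gene_rows),
        mirna_targets=mirna_table,
        tf_targets=tf_table,
        truth=truth,
        seed=seed,
        time_point=time_point,
    )


# ---------------------------------------------------------------------------
# serialisation


def write_dataset(ds: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Write the dataset as TSV files plus a YAML truth manifest."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, em in (
        ("mirna", ds.mirna_expr),
        ("tf", ds.tf_expr),
        ("gene", ds.gene_expr),
    ):
        v = d / f"{name}_expression.tsv"
        m = d / f"{name}_samples.tsv"
        em.to_tsv(v, m)
        paths[f"{name}_expression"] = v
        paths[f"{name}_samples"] = m
    ds.mirna_targets.to_tsv(d / "mirna_targets.tsv")
    ds.tf_targets.to_tsv(d / "tf_targets.tsv")
    paths["mirna_targets"] = d / "mirna_targets.tsv"
    paths["tf_targets"] = d / "tf_targets.tsv"
    manifest = {
        "seed": ds.seed,
        "time_point": ds.time_point,
        "n_triads": len(ds.truth),
        "truth": [
            {
                "mirna_id": t.mirna_id,
                "tf_id": t.tf_id,
                "gene_id": t.gene_id,
                "a": t.a,
                "b": t.b,
                "c_prime": t.c_prime,
                "noise_sd_m": t.noise_sd_m,
                "noise_sd_y": t.noise_sd_y,
                "intended_class": t.intended_class,
            }
            for t in ds.truth
        ],
    }
    mp = d / "manifest.yaml"
    mp.write_text(yaml.safe_dump(manifest, sort_keys=False))
    paths["manifest"] = mp
    return paths


def read_dataset(directory: str | Path) -> SyntheticDataset:
    d = Path(directory)
    manifest = yaml.safe_load((d / "manifest.yaml").read_text())
    truth = [TriadSpec(**row) for row in manifest["truth"]]
    return SyntheticDataset(
        mirna_expr=ExpressionMatrix.from_tsv(d / "mirna_expression.tsv", d / "mirna_samples.tsv"),
        tf_expr=ExpressionMatrix.from_tsv(d / "tf_expression.tsv", d / "tf_samples.tsv"),
        gene_expr=ExpressionMatrix.from_tsv(d / "gene_expression.tsv", d / "gene_samples.tsv"),
        mirna_targets=TargetTable.from_tsv(d / "mirna_targets.tsv"),
        tf_targets=TargetTable.from_tsv(d / "tf_targets.tsv"),
        truth=truth,
        seed=int(manifest["seed"]),
        time_point=str(manifest["time_point"]),
    )
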