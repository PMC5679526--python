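"""Normalisation, differential expression, imputation, probe collapsing.

The preprocessing stages mirror a standard single-colour microarray
workflow: per-chip 75th-percentile scaling followed by per-gene median
centring; an injured-vs-sham differential-expression filter at |fold
change| >= 2 with Benjamini-Hochberg corrected p <= 0.05; per-entity
least-squares imputation of unobserved time points; and collapsing of
multi-probe genes onto the first listed probe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix

FC_THRESHOLD = 2.0
ALPHA = 0.05


@dataclass
class DERecord:
    """Differential-expression call for one entity at one time point.

    ``fc`` is the injured/sham ratio of means on the linear scale, with
    down-regulation reported as the negative reciprocal so that the
    absolute-fold-change threshold is symmetric (fc = 0.25 -> -4).
    """

    entity_id: str
    fc: float
    raw_p: float
    bh_p: float
    passes: bool


def bh_adjust(raw_p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(raw_p, dtype=float), method="fdr_bh")[1]


def signed_fold_change(ratio: float) -> float:
    """Map a linear-scale ratio to the signed convention (<1 -> -1/ratio)."""
    if ratio <= 0:
        raise ValueError(f"fold-change ratio must be positive, got {ratio}")
    return ratio if ratio >= 1 else -1.0 / ratio


def normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Per-chip 75th-percentile scaling, then per-gene median centring.

    Step 1 divides each sample column by its own 75th percentile; step 2
    divides each entity row by its median across samples. Idempotent to
    numerical precision on its own output.
    """
    values = matrix.values.astype(float)
    q75 = values.quantile(0.75, axis=0)
    bad = q75[q75 <= 0]
    if len(bad):
        raise ValueError(
            f"non-positive 75th percentile in column(s): {list(bad.index)[:5]}"
        )
    scaled = values.div(q75, axis=1)
    med = scaled.median(axis=1)
    if (med == 0).any():
        raise ValueError("zero row median; cannot median-centre")
    centred = scaled.div(med, axis=0)
    return ExpressionMatrix(centred, matrix.sample_meta)


def differential_expression(
    matrix: ExpressionMatrix,
    time_point: str,
    fc_threshold: float = FC_THRESHOLD,
    alpha: float = ALPHA,
) -> list[DERecord]:
    """Call DE entities at one time point (injured vs sham).

    Fold change is the ratio of group means; the raw p-value comes from a
    Welch two-sample t-test per entity and is corrected across all tested
    entities by Benjamini-Hochberg. An entity passes when
    |signed fc| >= ``fc_threshold`` and BH p <= ``alpha``.
    """
    inj = matrix.subset_samples(condition="injured", time_point=time_point)
    sham = matrix.subset_samples(condition="sham", time_point=time_point)
    if inj.n_samples < 2 or sham.n_samples < 2:
        raise ValueError(
            f"need >= 2 replicates per group at {time_point!r}; "
            f"got {inj.n_samples} injured, {sham.n_samples} sham"
        )
    a = inj.values.to_numpy(dtype=float)
    b = sham.values.to_numpy(dtype=float)
    mean_inj = a.mean(axis=1)
    mean_sham = b.mean(axis=1)
    if (mean_inj <= 0).any() or (mean_sham <= 0).any():
        raise ValueError("group means must be positive for fold-change calls")
    ratio = mean_inj / mean_sham
    with np.errstate(invalid="ignore"):
        tstat, raw_p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    raw_p = np.where(np.isnan(raw_p), 1.0, raw_p)
    bh_p = multipletests(raw_p, method="fdr_bh")[1]
    records = []
    for eid, r, rp, bp in zip(matrix.entity_ids, ratio, raw_p, bh_p):
        fc = signed_fold_change(float(r))
        passes = abs(fc) >= fc_threshold and bp <= alpha
        records.append(DERecord(eid, fc, float(rp), float(bp), bool(passes)))
    return records


def de_frame(records: list[DERecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.entity_id, r.fc, r.raw_p, r.bh_p, r.passes) for r in records],
        columns=["entity_id", "fc", "raw_p", "bh_p", "passes"],
    )


def impute_timepoints(
    matrix: ExpressionMatrix,
    observed_times: dict[str, float],
    target_times: dict[str, float],
    condition: str | None = None,
) -> ExpressionMatrix:
    """Impute expression at unobserved time points by a per-entity OLS line.

    ``observed_times`` / ``target_times`` map time-point labels to numeric
    times. For every entity, expression (averaged over replicates within a
    time point) is regressed on numeric time; target time points get the
    fitted predictions as single new columns. Observed columns are
    unchanged.
    """
    if len(observed_times) < 2:
        raise ValueError("need >= 2 observed time points to fit a line")
    sub = matrix if condition is None else matrix.subset_samples(condition=condition)
    labels = list(observed_times)
    means = {}
    for lab in labels:
        cols = sub.sample_meta.index[sub.sample_meta["time_point"].astype(str) == lab]
        if len(cols) == 0:
            raise ValueError(f"no samples at observed time point {lab!r}")
        means[lab] = sub.values[cols].mean(axis=1)
    t = np.array([observed_times[lab] for lab in labels], dtype=float)
    y = np.column_stack([means[lab] for lab in labels])  # entities x times
    # per-entity line y = b0 + b1 t by closed-form OLS
    tc = t - t.mean()
    denom = (tc**2).sum()
    slope = (y * tc).sum(axis=1) / denom
    intercept = y.mean(axis=1) - slope * t.mean()

    values = matrix.values.copy()
    meta = matrix.sample_meta.copy()
    cond = condition if condition is not None else "injured"
    for lab, tt in target_times.items():
        col = f"imputed_{lab}_{cond}"
        values[col] = intercept + slope * tt
        meta.loc[col] = {"time_point": lab, "condition": cond, "replicate": 0}
    return ExpressionMatrix(values, meta)


def collapse_probes(
    matrix: ExpressionMatrix, probe_order: dict[str, list[str]]
) -> ExpressionMatrix:
    """Collapse multi-probe genes onto their first listed probe.

    ``probe_order`` maps gene id -> ordered probe ids (matrix rows). Each
    output row is the first listed probe's row, relabelled by gene id;
    genes not mentioned keep their single row unchanged.
    """
    mapped_probes = {p for probes in probe_order.values() for p in probes}
    missing = mapped_probes - set(matrix.entity_ids)
    if missing:
        raise ValueError(f"probe(s) absent from matrix: {sorted(missing)[:5]}")
    rows = {}
    for gene, probes in probe_order.items():
        if not probes:
            raise ValueError(f"empty probe list for gene {gene!r}")
        rows[gene] = matrix.values.loc[probes[0]]
    for eid in matrix.entity_ids:
        if eid not in mapped_probes:
            rows[eid] = matrix.values.loc[eid]
    out = pd.DataFrame(rows).T
    out.columns = matrix.values.columns
    return ExpressionMatrix(out, matrix.sample_meta)
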