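"""Edge screening by Pearson and distance correlation.

Every candidate loop carries three edges (miRNA->TF, miRNA->gene,
TF->gene). Each edge is scored with the Pearson product-moment correlation
and with distance correlation (dcor); significance of dependence is
decided by the distance-correlation t-test of independence, whose
bias-corrected statistic is approximately Student t with n(n-3)/2 - 1
degrees of freedom. Loops are retained only when all three edges are
significant; the Pearson p-value labels each edge linear vs nonlinear for
downstream model routing.

Distance correlation is implemented here directly (double centering for
the sample coefficient, U-centering for the unbiased statistic behind the
t-test).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .expression import ExpressionMatrix
from .loops import CandidateLoop

logger = logging.getLogger(__name__)

EDGE_NAMES = ("mirna_tf", "mirna_gene", "tf_gene")


def _as_vector(x) -> np.ndarray:
    v = np.asarray(x, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty vector")
    return v


def pearson_edge(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided t-based p-value.

    p is computed from t = r * sqrt((n-2)/(1-r^2)) with n-2 degrees of
    freedom, the classical test of zero correlation.
    """
    x, y = _as_vector(x), _as_vector(y)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector has undefined Pearson correlation")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _pairwise_abs_diff(v: np.ndarray) -> np.ndarray:
    return np.abs(v[:, None] - v[None, :])


def distance_correlation(x, y) -> float:
    """Sample distance correlation in [0, 1].

    Double-centres the two pairwise-distance matrices and returns
    sqrt(dcov^2 / sqrt(dvar_x * dvar_y)). Zero (population) iff x and y are
    independent; sensitive to nonlinear dependence. A constant vector has
    zero distance variance; dcor is then defined as 0 with a warning.
    """
    x, y = _as_vector(x), _as_vector(y)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 4:
        raise ValueError("need at least 4 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: distance correlation defined as 0")
        return 0.0
    A = _double_centre(_pairwise_abs_diff(x))
    B = _double_centre(_pairwise_abs_diff(y))
    dcov2 = (A * B).mean()
    dvar_x = (A * A).mean()
    dvar_y = (B * B).mean()
    denom = np.sqrt(dvar_x * dvar_y)
    if denom <= 0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / denom))


def _double_centre(d: np.ndarray) -> np.ndarray:
    return d - d.mean(axis=0) - d.mean(axis=1)[:, None] + d.mean()


def _u_centre(d: np.ndarray) -> np.ndarray:
    # U-centering: row/col sums over n-2, grand sum over (n-1)(n-2), zero diagonal
    n = d.shape[0]
    row = d.sum(axis=1)
    total = d.sum()
    u = d - row[None, :] / (n - 2) - row[:, None] / (n - 2) + total / ((n - 1) * (n - 2))
    np.fill_diagonal(u, 0.0)
    return u


def bias_corrected_dcor(x, y) -> float:
    """Bias-corrected distance correlation (can be negative).

    Uses U-centred distance matrices; under independence the statistic is
    centred at zero, which is what the t-test requires.
    """
    x, y = _as_vector(x), _as_vector(y)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 samples")
    A = _u_centre(_pairwise_abs_diff(x))
    B = _u_centre(_pairwise_abs_diff(y))
    xy = (A * B).sum()
    xx = (A * A).sum()
    yy = (B * B).sum()
    if xx <= 0 or yy <= 0:
        return 0.0
    return float(xy / np.sqrt(xx * yy))


def dcor_ttest(x, y) -> tuple[float, int, float]:
    """Distance-correlation t-test of independence.

    Returns (t statistic, degrees of freedom, one-sided p). The
    bias-corrected dcor r gives t = sqrt(df) * r / sqrt(1 - r^2) with
    df = n(n-3)/2 - 1; p is the upper-tail Student-t probability. The t
    approximation is intended for n >= 10; smaller n triggers a warning.
    """
    x, y = _as_vector(x), _as_vector(y)
    n = x.size
    if n < 10:
        warnings.warn(f"dcor t-test approximation is intended for n >= 10 (n={n})")
    df = n * (n - 3) // 2 - 1
    if df < 1:
        raise ValueError(f"too few samples for the dcor t-test (n={n})")
    r = bias_corrected_dcor(x, y)
    r = min(max(r, -0.999999999), 0.999999999)
    t = np.sqrt(df) * r / np.sqrt(1.0 - r * r)
    p = float(stats.t.sf(t, df))
    return float(t), int(df), p


@dataclass
class EdgeStats:
    """Correlation summary for one directed loop edge."""

    edge: tuple[str, str]
    n: int
    pearson_r: float
    pearson_p: float
    dcor: float
    dcor_stat: float
    dcor_df: int
    dcor_p: float
    linear: bool


@dataclass
class ScreenedLoop:
    loop: CandidateLoop
    edge_stats: tuple[EdgeStats, EdgeStats, EdgeStats]
    retained: bool = True
    # model routing for mediation: mediator model follows the miRNA->TF
    # edge, outcome model is linear only if both edges into the gene are
    edge_linear: dict = field(default_factory=dict)

    @property
    def kind_m(self) -> str:
        return "linear" if self.edge_stats[0].linear else "spline"

    @property
    def kind_y(self) -> str:
        return (
            "linear"
            if self.edge_stats[1].linear and self.edge_stats[2].linear
            else "spline"
        )


def edge_stats(x, y, edge: tuple[str, str], alpha: float = 0.05) -> EdgeStats:
    """Score one edge with Pearson + dcor and the dcor t-test."""
    x, y = _as_vector(x), _as_vector(y)
    r, pr = pearson_edge(x, y)
    dc = distance_correlation(x, y)
    t, df, p = dcor_ttest(x, y)
    return EdgeStats(
        edge=edge,
        n=x.size,
        pearson_r=r,
        pearson_p=pr,
        dcor=dc,
        dcor_stat=t,
        dcor_df=df,
        dcor_p=p,
        linear=bool(pr <= alpha),
    )


def screen_loops(
    loops: list[CandidateLoop],
    mirna_expr: ExpressionMatrix,
    tf_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> list[ScreenedLoop]:
    """Retain loops whose three edges all pass the dcor t-test at ``alpha``.

    Loops referencing an entity with no expression row are skipped and
    logged, not fatal. With ``bh_correct`` the edge p-values are
    Benjamini-Hochberg adjusted across all edges of all loops before the
    threshold is applied (off by default: the filter is a plain per-edge
    p <= alpha).
    """
    prelim: list[ScreenedLoop] = []
    for loop in loops:
        try:
            x = mirna_expr.row(loop.mirna_id)
            m = tf_expr.row(loop.tf_id)
            y = gene_expr.row(loop.gene_id)
        except KeyError as err:
            logger.warning("loop %s skipped: missing expression row %s", loop, err)
            continue
        es = (
            edge_stats(x, m, (loop.mirna_id, loop.tf_id), alpha),
            edge_stats(x, y, (loop.mirna_id, loop.gene_id), alpha),
            edge_stats(m, y, (loop.tf_id, loop.gene_id), alpha),
        )
        prelim.append(ScreenedLoop(loop, es))

    if bh_correct and prelim:
        from statsmodels.stats.multitest import multipletests

        ps = [e.dcor_p for sl in prelim for e in sl.edge_stats]
        adj = multipletests(ps, method="fdr_bh")[1]
        it = iter(adj)
        for sl in prelim:
            for e in sl.edge_stats:
                e.dcor_p = float(next(it))

    retained = []
    for sl in prelim:
        if all(e.dcor_p <= alpha for e in sl.edge_stats):
            retained.append(sl)
    return retained


def screened_frame(screened: list[ScreenedLoop]):
    """Long-to-wide TSV-ready table: one row per loop, 5 stats per edge."""
    import pandas as pd

    rows = []
    for sl in screened:
        row = {
            "mirna_id": sl.loop.mirna_id,
            "tf_id": sl.loop.tf_id,
            "gene_id": sl.loop.gene_id,
        }
        for name, e in zip(EDGE_NAMES, sl.edge_stats):
            row.update(
                {
                    f"{name}_r": e.pearson_r,
                    f"{name}_p_r": e.pearson_p,
                    f"{name}_dcor": e.dcor,
                    f"{name}_p_dcor": e.dcor_p,
                    f"{name}_linear": e.linear,
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)
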