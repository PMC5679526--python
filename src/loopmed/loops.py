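"""Closed regulatory loop inference from regulator->target tables.

A closed loop is a triad in which a miRNA targets both a transcription
factor and a gene while the same TF also targets that gene: the three
directed edges miRNA->TF, miRNA->gene and TF->gene close a triangle over
three distinct nodes. Candidate loops are the triple join of the miRNA- and
TF-target tables restricted to a universe of (typically differentially
expressed) entities.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

TABLE_COLUMNS = ["regulator_id", "regulator_kind", "target_id", "target_kind", "source", "score"]

EDGE_TYPES = ("mirna_tf", "mirna_gene", "tf_gene")


@dataclass(frozen=True, order=True)
class CandidateLoop:
    """Ordered triad (miRNA, TF, gene) with its three implied edges."""

    mirna_id: str
    tf_id: str
    gene_id: str

    def __post_init__(self) -> None:
        if len({self.mirna_id, self.tf_id, self.gene_id}) != 3:
            raise ValueError(f"loop nodes must be distinct: {self}")

    @property
    def edges(self) -> list[tuple[str, str, str]]:
        """The three directed edges as (source, target, edge_type)."""
        return [
            (self.mirna_id, self.tf_id, "mirna_tf"),
            (self.mirna_id, self.gene_id, "mirna_gene"),
            (self.tf_id, self.gene_id, "tf_gene"),
        ]


class TargetTable:
    """De-duplicated directed regulator->target pair records.

    Rows arriving from multiple databases for the same (regulator, target)
    pair are merged: sources are pooled (comma-joined, sorted) and the best
    (most negative, mirSVR-like) score is kept. Self-targeting rows are
    dropped since triads require distinct nodes.
    """

    def __init__(self, records: pd.DataFrame):
        df = records.copy()
        for col in ("source", "score"):
            if col not in df.columns:
                df[col] = "" if col == "source" else float("nan")
        df = df[TABLE_COLUMNS]
        df = df[df["regulator_id"] != df["target_id"]]
        df = (
            df.groupby(["regulator_id", "regulator_kind", "target_id", "target_kind"], sort=True)
            .agg(
                source=("source", lambda s: ",".join(sorted(set(map(str, s))))),
                score=("score", "min"),
            )
            .reset_index()
        )
        self.records = df
        self._pairs = set(zip(df["regulator_id"], df["target_id"]))

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self._pairs

    def targets_of(self, regulator_id: str, target_kind: str | None = None) -> set[str]:
        df = self.records
        mask = df["regulator_id"] == regulator_id
        if target_kind is not None:
            mask &= df["target_kind"] == target_kind
        return set(df.loc[mask, "target_id"])

    def regulators(self) -> list[str]:
        return sorted(self.records["regulator_id"].unique())

    def kinds_of(self) -> dict[str, set[str]]:
        """Map each identifier to the set of kinds it appears under."""
        kinds: dict[str, set[str]] = {}
        for _, r in self.records.iterrows():
            kinds.setdefault(r["regulator_id"], set()).add(r["regulator_kind"])
            kinds.setdefault(r["target_id"], set()).add(r["target_kind"])
        return kinds

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TargetTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"regulator_id": str, "target_id": str}))


def infer_closed_loops(
    mirna_targets: TargetTable,
    tf_targets: TargetTable,
    universe: dict[str, set[str]] | None = None,
) -> list[CandidateLoop]:
    """Enumerate every closed miRNA->TF->gene triad in the tables.

    Returns exactly the set {(mi, tf, g) : mi->tf and mi->g in
    ``mirna_targets``, tf->g in ``tf_targets``}, optionally restricted to
    ``universe`` (a dict with key sets ``mirna``, ``tf``, ``gene``), sorted
    lexicographically by (mirna, tf, gene).

    Raises
    ------
    ValueError
        If an identifier is used with inconsistent kinds (e.g. appears both
        as a miRNA and as a gene), making the triad roles ambiguous.
    """
    kinds: dict[str, set[str]] = {}
    for table in (mirna_targets, tf_targets):
        for ident, ks in table.kinds_of().items():
            kinds.setdefault(ident, set()).update(ks)
    ambiguous = {i for i, ks in kinds.items() if "miRNA" in ks and "gene" in ks}
    if ambiguous:
        raise ValueError(
            f"identifiers used as both miRNA and gene: {sorted(ambiguous)[:5]}"
        )

    def keep(ident: str, role: str) -> bool:
        return universe is None or ident in universe.get(role, set())

    loops: list[CandidateLoop] = []
    for mi in mirna_targets.regulators():
        if not keep(mi, "mirna"):
            continue
        tf_hits = mirna_targets.targets_of(mi, target_kind="TF")
        gene_hits = mirna_targets.targets_of(mi, target_kind="gene")
        gene_hits = {g for g in gene_hits if keep(g, "gene")}
        for tf in sorted(tf_hits):
            if not keep(tf, "tf"):
                continue
            common = gene_hits & tf_targets.targets_of(tf, target_kind="gene")
            for g in sorted(common):
                if len({mi, tf, g}) == 3:
                    loops.append(CandidateLoop(mi, tf, g))
    return sorted(loops)


def loops_to_graph(loops: list[CandidateLoop]) -> nx.DiGraph:
    """Merge loop edges into one directed simple graph.

    Node attribute ``kind`` is one of miRNA/TF/gene; duplicate edges from
    loops sharing an edge are merged (union semantics).
    """
    g = nx.DiGraph()
    for loop in loops:
        g.add_node(loop.mirna_id, kind="miRNA")
        g.add_node(loop.tf_id, kind="TF")
        g.add_node(loop.gene_id, kind="gene")
        for u, v, etype in loop.edges:
            g.add_edge(u, v, edge_type=etype)
    return g


def loops_to_frame(loops: list[CandidateLoop]) -> pd.DataFrame:
    return pd.DataFrame(
        [(l.mirna_id, l.tf_id, l.gene_id) for l in loops],
        columns=["mirna_id", "tf_id", "gene_id"],
    )


def write_loops(loops: list[CandidateLoop], path: str | Path) -> None:
    loops_to_frame(loops).to_csv(path, sep="\t", index=False)


def read_loops(path: str | Path) -> list[CandidateLoop]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [CandidateLoop(r.mirna_id, r.tf_id, r.gene_id) for r in df.itertuples()]


def write_graph_edgelist(g: nx.DiGraph, path: str | Path) -> None:
    rows = [(u, v, d.get("edge_type", "")) for u, v, d in g.edges(data=True)]
    pd.DataFrame(rows, columns=["source", "target", "edge_type"]).to_csv(
        path, sep="\t", index=False
    )
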