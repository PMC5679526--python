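"""Classification of mediated loops and summary tables.

A screened loop whose mediation result has a significant ACME only is
TF-mediated (M_T); significant ADE only is miRNA-mediated (M_M); both
significant is co-mediated (M_TM); neither is UNEXPLAINED. M_TM loops are
sub-classified by whether ACME and ADE share a sign (supporting vs
opposing) and by which regulator's fold-change direction the target gene
follows. Direction tables and top-effect extraction summarise a cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import pandas as pd

from .loops import CandidateLoop
from .mediation import MediationResult

CLASSES = ("M_T", "M_M", "M_TM", "UNEXPLAINED")


def _sign(v: float) -> str:
    if v > 0:
        return "+"
    if v < 0:
        return "-"
    return "0"


@dataclass
class LoopClassification:
    loop: CandidateLoop
    cls: str
    acme: float
    ade: float
    acme_sign: str
    ade_sign: str
    agreement: str = "n/a"  # supporting | opposing | n/a
    tg_follows: str = "n/a"  # miRNA | TF | both | neither | n/a
    fc_mirna: float = float("nan")
    fc_tf: float = float("nan")
    fc_gene: float = float("nan")


def classify(
    result: MediationResult,
    alpha: float = 0.05,
    fc_mirna: float = float("nan"),
    fc_tf: float = float("nan"),
    fc_gene: float = float("nan"),
) -> LoopClassification:
    """Assign one loop to M_T / M_M / M_TM / UNEXPLAINED by p-values.

    M_T: acme_p <= alpha and ade_p > alpha; M_M: the reverse; M_TM: both
    significant; otherwise UNEXPLAINED (the loop is not explained by the
    mediation model). Exactly one rule applies.
    """
    acme_sig = result.acme_p <= alpha
    ade_sig = result.ade_p <= alpha
    if acme_sig and ade_sig:
        cls = "M_TM"
    elif acme_sig:
        cls = "M_T"
    elif ade_sig:
        cls = "M_M"
    else:
        cls = "UNEXPLAINED"
    return LoopClassification(
        loop=result.loop,
        cls=cls,
        acme=result.acme,
        ade=result.ade,
        acme_sign=_sign(result.acme),
        ade_sign=_sign(result.ade),
        fc_mirna=fc_mirna,
        fc_tf=fc_tf,
        fc_gene=fc_gene,
    )


def subclassify_mtm(c: LoopClassification) -> LoopClassification:
    """Sub-classify a co-mediated (M_TM) loop.

    agreement: supporting when ACME and ADE share a sign, opposing
    otherwise. For opposing loops the target gene's fold-change direction
    is compared against the miRNA's (tg_follows = miRNA) or else the TF's;
    for supporting loops, tg_follows = both when the gene, miRNA and TF
    all move in the same direction, else neither.
    """
    if c.cls != "M_TM":
        raise ValueError("subclassification applies to M_TM loops only")
    if c.acme == 0 or c.ade == 0:
        warnings.warn(f"zero effect in {c.loop}: agreement undefined")
        return replace(c, agreement="n/a", tg_follows="n/a")
    agreement = "supporting" if _sign(c.acme) == _sign(c.ade) else "opposing"
    sg, smi, stf = _sign(c.fc_gene), _sign(c.fc_mirna), _sign(c.fc_tf)
    if agreement == "opposing":
        tg_follows = "miRNA" if sg == smi else "TF"
    else:
        tg_follows = "both" if (sg == smi == stf) else "neither"
    return replace(c, agreement=agreement, tg_follows=tg_follows)


def direction_tables(classified: list[LoopClassification]) -> dict[str, pd.DataFrame]:
    """Count tables of fold-change direction patterns per class.

    For M_T loops: counts where TF and target gene move together, split
    up/up vs down/down (other patterns counted as 'other'). For M_M
    loops: counts where miRNA and gene move oppositely, split by which is
    up. For M_TM: supporting vs opposing, and the tg_follows breakdown.
    """
    mt = [c for c in classified if c.cls == "M_T"]
    mm = [c for c in classified if c.cls == "M_M"]
    mtm = [c for c in classified if c.cls == "M_TM"]

    mt_counts = {
        "up_TF_up_TG": sum(1 for c in mt if _sign(c.fc_tf) == _sign(c.fc_gene) == "+"),
        "down_TF_down_TG": sum(1 for c in mt if _sign(c.fc_tf) == _sign(c.fc_gene) == "-"),
    }
    mt_counts["other"] = len(mt) - sum(mt_counts.values())

    mm_counts = {
        "down_miRNA_up_TG": sum(
            1 for c in mm if _sign(c.fc_mirna) == "-" and _sign(c.fc_gene) == "+"
        ),
        "up_miRNA_down_TG": sum(
            1 for c in mm if _sign(c.fc_mirna) == "+" and _sign(c.fc_gene) == "-"
        ),
    }
    mm_counts["other"] = len(mm) - sum(mm_counts.values())

    sub = [subclassify_mtm(c) if c.agreement == "n/a" and c.cls == "M_TM" else c for c in mtm]
    mtm_counts = {
        "opposing": sum(1 for c in sub if c.agreement == "opposing"),
        "supporting": sum(1 for c in sub if c.agreement == "supporting"),
    }
    opp = [c for c in sub if c.agreement == "opposing"]
    sup = [c for c in sub if c.agreement == "supporting"]
    follows = {
        "opposing_TG_follows_miRNA": sum(1 for c in opp if c.tg_follows == "miRNA"),
        "opposing_TG_follows_TF": sum(1 for c in opp if c.tg_follows == "TF"),
        "supporting_TG_follows_both": sum(1 for c in sup if c.tg_follows == "both"),
        "supporting_TG_opposes_both": sum(1 for c in sup if c.tg_follows == "neither"),
    }
    return {
        "M_T": pd.DataFrame([mt_counts]),
        "M_M": pd.DataFrame([mm_counts]),
        "M_TM": pd.DataFrame([mtm_counts]),
        "M_TM_follows": pd.DataFrame([follows]),
    }


def class_counts(classified: list[LoopClassification]) -> pd.DataFrame:
    """Per-class loop counts plus the fraction explained by mediation."""
    counts = {cls: sum(1 for c in classified if c.cls == cls) for cls in CLASSES}
    total = len(classified)
    explained = total - counts["UNEXPLAINED"]
    counts["total"] = total
    counts["explained"] = explained
    counts["explained_fraction"] = explained / total if total else float("nan")
    return pd.DataFrame([counts])


def top_effects(
    results: list[MediationResult],
    classified: list[LoopClassification],
    k: int = 5,
) -> pd.DataFrame:
    """Top-k highest and lowest ACME and ADE per loop class.

    Ties broken lexicographically by loop identity; classes smaller than
    k return all members flagged ``short``.
    """
    by_loop = {c.loop: c.cls for c in classified}
    rows = []
    for cls in ("M_T", "M_M", "M_TM"):
        members = [r for r in results if by_loop.get(r.loop) == cls]
        short = len(members) < k
        for effect in ("acme", "ade"):
            def key(r, _e=effect):
                return (getattr(r, _e), (r.loop.mirna_id, r.loop.tf_id, r.loop.gene_id))

            ranked = sorted(members, key=key)
            for label, sel in (("lowest", ranked[:k]), ("highest", ranked[-k:][::-1])):
                for rank, r in enumerate(sel, 1):
                    rows.append(
                        {
                            "class": cls,
                            "effect": effect,
                            "which": label,
                            "rank": rank,
                            "mirna_id": r.loop.mirna_id,
                            "tf_id": r.loop.tf_id,
                            "gene_id": r.loop.gene_id,
                            "value": getattr(r, effect),
                            "short": short,
                        }
                    )
    return pd.DataFrame(rows)


def classification_frame(classified: list[LoopClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna_id": c.loop.mirna_id,
                "tf_id": c.loop.tf_id,
                "gene_id": c.loop.gene_id,
                "class": c.cls,
                "acme": c.acme,
                "ade": c.ade,
                "acme_sign": c.acme_sign,
                "ade_sign": c.ade_sign,
                "agreement": c.agreement,
                "tg_follows": c.tg_follows,
                "fc_mirna": c.fc_mirna,
                "fc_tf": c.fc_tf,
                "fc_gene": c.fc_gene,
            }
            for c in classified
        ]
    )
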