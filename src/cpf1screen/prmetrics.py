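"""Precision-recall benchmarking of Bayes-factor rankings.

The AUC used throughout is *average precision* (sum of precision over recall
increments, no trapezoidal interpolation): its expectation under a random
ranking equals the prevalence of positives, which for the 342-essential /
345-non-essential benchmark sets is 342/687 = 0.498 — the null baseline that
anchors the mAUC/rmAUC separation-rate metrics.

Only reference genes enter a curve; other genes may be scored but are
ignored here.  Ties in BF are kept in stable input order and the whole tie
group receives the precision at the group's end (conservative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import ReferenceSets

logger = logging.getLogger(__name__)


@dataclass
class PRCurve:
    recall: np.ndarray
    precision: np.ndarray
    auc: float
    level: str = "gene"


def null_auc(refs: ReferenceSets) -> float:
    """Prevalence of positives — the expected average precision of a random ranking."""
    return refs.prevalence


def pr_curve(scores: pd.Series, refs: ReferenceSets, level: str = "gene") -> PRCurve:
    """Precision-recall curve of genes ranked by score (descending).

    ``scores`` must cover every reference gene; missing ones are an error.
    """
    scores = pd.Series(scores).astype(float)
    ref_genes = refs.all_genes
    missing = sorted(g for g in ref_genes if g not in scores.index)
    if missing:
        raise ValueError(f"reference genes without scores: {missing[:10]}")
    sub = scores[scores.index.isin(ref_genes)]
    order = np.argsort(-sub.to_numpy(), kind="stable")
    y = sub.index.isin(refs.essential)[order]
    s = sub.to_numpy()[order]

    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == y.size:
        raise ValueError("need both positives and negatives among scored reference genes")
    tp = np.cumsum(y)
    ranks = np.arange(1, y.size + 1)
    precision = tp / ranks
    recall = tp / n_pos

    # tie groups share the precision at the group's end
    is_group_end = np.r_[s[1:] != s[:-1], True]
    end_idx = np.empty(y.size, dtype=int)
    last = y.size - 1
    for i in range(y.size - 1, -1, -1):
        if is_group_end[i]:
            last = i
        end_idx[i] = last
    tie_precision = precision[end_idx]

    ap = float(tie_precision[y].sum() / n_pos)
    return PRCurve(recall=recall, precision=tie_precision, auc=ap, level=level)


def average_precision(scores: pd.Series, refs: ReferenceSets) -> float:
    return pr_curve(scores, refs).auc


@dataclass
class RmaucSeries:
    """Per-timepoint separation metrics relative to the endpoint.

    mAUC_x = AUC_x - null; rmAUC_x = mAUC_x / mAUC_end * 100%.
    """

    timepoints: list[int]
    auc: pd.Series  # indexed by timepoint
    null_auc: float
    mauc: pd.Series
    rmauc: pd.Series  # percent


def rmauc(aucs: dict[int, float] | pd.Series, null: float) -> RmaucSeries:
    """Ratio of modified AUC at each timepoint to the endpoint's, as a percentage."""
    auc = pd.Series(aucs).sort_index().astype(float)
    end = auc.index.max()
    auc_end = float(auc.loc[end])
    if auc_end <= null:
        raise ValueError(
            f"no endpoint separation: AUC_end={auc_end:.3f} <= null={null:.3f}"
        )
    mauc = auc - null
    return RmaucSeries(
        timepoints=list(auc.index),
        auc=auc,
        null_auc=null,
        mauc=mauc,
        rmauc=mauc / (auc_end - null) * 100.0,
    )


def down_sample(
    guide_table: pd.DataFrame,
    refs: ReferenceSets,
    guides_per_gene: int,
    n_draws: int = 10,
    seed: int | None = None,
) -> tuple[list[float], float]:
    """Randomly down-sample guides per gene and re-benchmark the gene ranking.

    ``guide_table`` needs columns ``gene`` and ``guide_bf`` (one row per
    guide).  Per draw, ``guides_per_gene`` guides are sampled without
    replacement from each gene, gene BFs re-summed, and the average
    precision over the reference sets computed.  Genes with too few guides
    are excluded with a warning.  Returns (per-draw AUCs, their mean).
    """
    if guides_per_gene < 1 or n_draws < 1:
        raise ValueError("guides_per_gene and n_draws must be >= 1")
    tbl = guide_table[["gene", "guide_bf"]].dropna()
    sizes = tbl.groupby("gene").size()
    too_few = sizes[sizes < guides_per_gene].index
    if len(too_few):
        logger.warning("excluding %d genes with < %d guides", len(too_few), guides_per_gene)
        tbl = tbl[~tbl["gene"].isin(too_few)]
    kept_refs = ReferenceSets(
        frozenset(g for g in refs.essential if g in set(tbl["gene"])),
        frozenset(g for g in refs.non_essential if g in set(tbl["gene"])),
    )
    rng = np.random.default_rng(seed)
    aucs: list[float] = []
    grouped = list(tbl.groupby("gene")["guide_bf"])
    for _ in range(n_draws):
        gene_bf = {
            gene: float(vals.to_numpy()[
                rng.choice(len(vals), size=guides_per_gene, replace=False)
            ].sum())
            for gene, vals in grouped
        }
        aucs.append(average_precision(pd.Series(gene_bf), kept_refs))
    return aucs, float(np.mean(aucs))
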