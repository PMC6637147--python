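"""Position-specific AsCpf1 protospacer preference scoring.

Within each essential gene of a mono-cistronic screen the most depleted
guide is labelled high-performing and the least depleted low-performing;
gene-wise pairing cancels gene-specific dropout severity, isolating sequence
preference.  Per bootstrap, genes (each carrying its high/low pair) are
resampled with replacement, nucleotide frequencies at each of the 20
protospacer positions are computed separately for the high and the low set,
and the score-table cell is freq(high) - freq(low); the final table is the
mean over bootstraps.  Position +1 is the protospacer base adjacent to the
PAM.  A guide's score is the sum of its 20 positional cells, and guides are
classified high-performing when the score is > 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .types import FoldChangeMatrix, GuideLibrary, ReferenceSets

logger = logging.getLogger(__name__)

NUCLEOTIDES = ("A", "C", "G", "T")
_NT_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}
GUIDE_LENGTH = 20


@dataclass
class ScoreTable:
    """4 x 20 nucleotide-preference matrix in frequency-difference units."""

    scores: pd.DataFrame  # index A,C,G,T; columns 1..20 (position, PAM-adjacent = 1)
    n_bootstraps: int
    sd: pd.DataFrame | None = None  # per-cell bootstrap s.d.

    def to_tsv(self, path) -> None:
        out = self.scores.copy()
        out.index.name = "nucleotide"
        out.to_csv(path, sep="\t", float_format="%.6f")

    @classmethod
    def from_tsv(cls, path) -> "ScoreTable":
        df = pd.read_csv(path, sep="\t", index_col="nucleotide")
        df.columns = df.columns.astype(int)
        return cls(scores=df.loc[list(NUCLEOTIDES)], n_bootstraps=0)


@dataclass
class ExtremePairs:
    """Per-gene high/low guide pair plus the held-out median guides."""

    pairs: pd.DataFrame  # index gene; columns high_guide, low_guide, high_lfc, low_lfc
    median: pd.DataFrame  # columns gene, guide, lfc (validation holdout)


def classify_extremes(
    fc: FoldChangeMatrix,
    library: GuideLibrary,
    essential_genes,
    timepoint: int | None = None,
) -> ExtremePairs:
    """Split each essential gene's guides into most/least depleted and the rest.

    Requires a mono-cistronic library (one construct per guide) and >= 3
    scored guides per gene; smaller genes are excluded with a warning.  Ties
    are broken toward the lower construct index (stable input order).
    """
    if not library.nuclease_mode.is_mono:
        raise ValueError("extreme classification requires a mono-cistronic library")
    lfc = fc.replicate_mean(timepoint)
    genes = library.construct_genes().reindex(lfc.index)
    seq = {c.construct_id: c.guides[0] for c in library.constructs}
    essential_genes = set(essential_genes)

    pair_rows, median_rows, skipped = {}, [], 0
    for gene, grp in lfc.groupby(genes):
        if gene not in essential_genes:
            continue
        if len(grp) < 3:
            skipped += 1
            continue
        vals = grp.to_numpy()
        hi_id = grp.index[int(np.argmin(vals))]  # most depleted
        lo_id = grp.index[int(np.argmax(vals))]  # least depleted
        pair_rows[gene] = (seq[hi_id], seq[lo_id], grp[hi_id], grp[lo_id])
        for cid in grp.index:
            if cid not in (hi_id, lo_id):
                median_rows.append((gene, seq[cid], grp[cid]))
    if skipped:
        logger.warning("excluded %d genes with < 3 scored guides", skipped)
    if not pair_rows:
        raise ValueError("no essential genes with >= 3 guides")
    pairs = pd.DataFrame.from_dict(
        pair_rows, orient="index",
        columns=["high_guide", "low_guide", "high_lfc", "low_lfc"],
    )
    pairs.index.name = "gene"
    return ExtremePairs(
        pairs=pairs,
        median=pd.DataFrame(median_rows, columns=["gene", "guide", "lfc"]),
    )


def _onehot(guides) -> np.ndarray:
    """(n, 4, 20) one-hot encoding of 20-mer protospacers."""
    arr = np.zeros((len(guides), 4, GUIDE_LENGTH))
    for i, g in enumerate(guides):
        if len(g) != GUIDE_LENGTH:
            raise ValueError(f"guide {g!r} is not a 20-mer")
        for p, base in enumerate(g):
            try:
                arr[i, _NT_INDEX[base], p] = 1.0
            except KeyError:
                raise ValueError(f"guide {g!r}: ambiguous base {base!r}") from None
    return arr


class ProtospacerScorer(BaseEstimator):
    """Bootstrap-averaged nucleotide-preference scorer for AsCpf1 protospacers.

    Parameters
    ----------
    n_bootstraps : int, default=100
        Gene-level resamples (with replacement, size preserved).
    random_state : int or None
        Seed for the bootstrap; identical seeds give identical tables.

    Attributes
    ----------
    score_table_ : ScoreTable
        Mean frequency-difference matrix with per-cell bootstrap s.d.
    """

    def __init__(self, n_bootstraps: int = 100, random_state: int | None = None):
        self.n_bootstraps = n_bootstraps
        self.random_state = random_state

    def fit(self, high_guides, low_guides):
        """Fit from paired high/low-performing 20-mers (one pair per gene)."""
        if self.n_bootstraps < 1:
            raise ValueError("n_bootstraps must be >= 1")
        high = list(high_guides)
        low = list(low_guides)
        if not high or len(high) != len(low):
            raise ValueError("need equal, non-empty high and low guide lists")
        oh_high = _onehot(high)
        oh_low = _onehot(low)
        n = len(high)
        rng = np.random.default_rng(self.random_state)
        tables = np.empty((self.n_bootstraps, 4, GUIDE_LENGTH))
        for b in range(self.n_bootstraps):
            idx = rng.integers(0, n, size=n)  # the pair travels together
            tables[b] = oh_high[idx].mean(axis=0) - oh_low[idx].mean(axis=0)
        cols = range(1, GUIDE_LENGTH + 1)
        self.score_table_ = ScoreTable(
            scores=pd.DataFrame(tables.mean(axis=0), index=list(NUCLEOTIDES), columns=cols),
            n_bootstraps=self.n_bootstraps,
            sd=pd.DataFrame(tables.std(axis=0, ddof=0), index=list(NUCLEOTIDES), columns=cols),
        )
        return self

    def score_guides(self, guides) -> np.ndarray:
        """Sum of positional cells for each guide."""
        oh = _onehot(list(guides))
        return (oh * self.score_table_.scores.to_numpy()).sum(axis=(1, 2))

    def predict(self, guides) -> np.ndarray:
        """'high' where score > 0, else 'low'."""
        return np.where(self.score_guides(guides) > 0, "high", "low")


def fit_score_table(pairs, n_bootstraps: int = 100, seed: int | None = None) -> ScoreTable:
    """Functional wrapper: list of (high, low) 20-mer pairs -> ScoreTable.

    Requires at least 30 pairs — fewer gives an unstable frequency estimate.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty pair list")
    if len(pairs) < 30:
        raise ValueError(f"need >= 30 high/low pairs, got {len(pairs)}")
    high, low = zip(*pairs)
    est = ProtospacerScorer(n_bootstraps=n_bootstraps, random_state=seed).fit(high, low)
    return est.score_table_


@dataclass
class GuideScore:
    guide: str
    score: float
    predicted_class: str  # "high" | "low"


def score_guide(guide: str, table: ScoreTable) -> GuideScore:
    """Score one 20-mer: sum of table cells at its bases; class by sign (> 0 = high)."""
    total = 0.0
    if len(guide) != GUIDE_LENGTH:
        raise ValueError(f"guide {guide!r} is not a 20-mer")
    for pos, base in enumerate(guide, start=1):
        if base not in _NT_INDEX:
            raise ValueError(f"guide {guide!r}: ambiguous base {base!r}")
        total += float(table.scores.loc[base, pos])
    return GuideScore(guide=guide, score=total,
                      predicted_class="high" if total > 0 else "low")


@dataclass
class ValidationReport:
    spearman_rho: float
    spearman_p: float
    mean_lfc_predicted_high: float
    mean_lfc_predicted_low: float
    t_statistic: float
    t_p: float
    n: int


def validate_on_holdout(median: pd.DataFrame, table: ScoreTable) -> ValidationReport:
    """Evaluate the table on held-out median-performing guides.

    ``median`` needs columns ``guide`` and ``lfc``.  Reports the Spearman
    correlation between score and fold change (expected negative: higher
    score -> deeper depletion) and the mean lfc of predicted-high vs
    predicted-low guides with a two-sided two-sample t statistic.
    """
    if len(median) < 10:
        raise ValueError("holdout too small (< 10 guides)")
    scores = np.array([score_guide(g, table).score for g in median["guide"]])
    lfc = median["lfc"].to_numpy(dtype=float)
    if np.ptp(scores) == 0:
        rho, rho_p = 0.0, 1.0
        hi_mean = lo_mean = float(lfc.mean())
        t, t_p = 0.0, 1.0
    else:
        rho, rho_p = stats.spearmanr(scores, lfc)
        hi = lfc[scores > 0]
        lo = lfc[scores <= 0]
        hi_mean = float(hi.mean()) if hi.size else float("nan")
        lo_mean = float(lo.mean()) if lo.size else float("nan")
        if hi.size >= 2 and lo.size >= 2:
            t, t_p = stats.ttest_ind(hi, lo)
        else:
            t, t_p = float("nan"), float("nan")
    return ValidationReport(
        spearman_rho=float(rho), spearman_p=float(rho_p),
        mean_lfc_predicted_high=hi_mean, mean_lfc_predicted_low=lo_mean,
        t_statistic=float(t), t_p=float(t_p), n=len(median),
    )
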