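"""Low Fat BAGEL: guide-level Bayesian essentiality classification.

The classic BAGEL approach fits fold-change distributions for gold-standard
essential and non-essential genes and scores every gene by a log2 Bayes
factor — the log-likelihood ratio of its fold change under the essential vs
the non-essential distribution.  Resampling at the *gene* level overfits on
small libraries, so this variant resamples at the level of individual
guides/constructs: across permutations, roughly 60% of the reference guides
are drawn (without replacement) as a training set, Gaussian kernel densities
are fitted to the training fold changes of each class, and Bayes factors are
computed for every held-out reference guide and every non-reference guide.
Each guide's final BF is its mean over the permutations in which it was
scored; a gene's BF is the sum of its guides' mean BFs.  For a multiplexed
library each gene has a single construct, so construct-level and gene-level
BFs coincide.

Numerical stabilization follows BAGEL practice: both densities are floored
at a small constant before taking the log ratio, and evaluation is clamped
to the interval where both training densities stay above the floor
(additionally bounded to one log2 unit beyond the training data range).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.base import BaseEstimator

from .types import FoldChangeMatrix, GuideLibrary, ReferenceSets

logger = logging.getLogger(__name__)

DENSITY_FLOOR = 1e-12
_CLAMP_GRID = 2001
_MIN_TRAIN = 20
_MIN_REFERENCE_GUIDES = 50


@dataclass
class DensityPair:
    """Fitted essential / non-essential fold-change densities with clamp bounds."""

    essential_density: gaussian_kde
    nonessential_density: gaussian_kde
    lfc_lo: float
    lfc_hi: float
    floor: float = DENSITY_FLOOR


def fit_densities(
    train_essential_lfc,
    train_nonessential_lfc,
    floor: float = DENSITY_FLOOR,
) -> DensityPair:
    """Gaussian-KDE fits (Scott's-rule bandwidth) for the two training classes.

    The evaluation interval is where both densities are at least ``floor``,
    intersected with [min(train) - 1, max(train) + 1].
    """
    e = np.asarray(train_essential_lfc, dtype=float)
    n = np.asarray(train_nonessential_lfc, dtype=float)
    if e.size < _MIN_TRAIN or n.size < _MIN_TRAIN:
        raise ValueError(
            f"need >= {_MIN_TRAIN} training values per class, got {e.size}/{n.size}"
        )
    if np.ptp(e) == 0 or np.ptp(n) == 0:
        raise ValueError("degenerate (zero-variance) training set")
    kde_e = gaussian_kde(e)
    kde_n = gaussian_kde(n)
    lo = min(e.min(), n.min()) - 1.0
    hi = max(e.max(), n.max()) + 1.0
    grid = np.linspace(lo, hi, _CLAMP_GRID)
    ok = (kde_e(grid) >= floor) & (kde_n(grid) >= floor)
    if not ok.any():
        raise ValueError("densities never jointly exceed the floor")
    return DensityPair(
        essential_density=kde_e,
        nonessential_density=kde_n,
        lfc_lo=float(grid[ok].min()),
        lfc_hi=float(grid[ok].max()),
        floor=floor,
    )


def guide_bf(lfc, dp: DensityPair):
    """log2 Bayes factor at (clamped) lfc: log2(f_ess / f_non), densities floored.

    Accepts a scalar or an array; returns the same shape.
    """
    x = np.clip(np.asarray(lfc, dtype=float), dp.lfc_lo, dp.lfc_hi)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    fe = np.maximum(dp.essential_density(x), dp.floor)
    fn = np.maximum(dp.nonessential_density(x), dp.floor)
    bf = np.log2(fe / fn)
    return float(bf[0]) if scalar else bf


@dataclass(frozen=True)
class BootstrapScheme:
    """Guide-level resampling plan: how many permutations, training fraction, seed."""

    n_permutations: int = 100
    train_fraction: float = 0.60
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0.0 < self.train_fraction <= 1.0:
            raise ValueError("train_fraction must be in (0, 1]")


@dataclass
class BayesFactorTable:
    """Per-guide and per-gene log2 Bayes factors."""

    guide_table: pd.DataFrame  # index guide_id; columns gene, guide_bf, n_permutations_scored
    gene_bf: pd.Series  # index gene
    nontargeting_label: str | None = field(default=None)

    def to_tsv(self, path) -> None:
        out = self.guide_table.copy()
        out["gene_bf"] = out["gene"].map(self.gene_bf)
        out.index.name = "guide_id"
        out.to_csv(path, sep="\t", float_format="%.6f")


class LowFatBagel(BaseEstimator):
    """Small-library Bayes-factor essentiality classifier.

    Parameters
    ----------
    n_permutations : int, default=100
        Number of training/test resampling rounds.
    train_fraction : float, default=0.6
        Fraction of reference guides (per class) drawn without replacement
        as training data in each permutation.  1.0 trains on the full
        reference set and scores everything (no held-out round).
    density_floor : float, default=1e-12
        Lower bound applied to both kernel densities before the log ratio.
    random_state : int or None
        Seed; identical seeds give identical Bayes-factor tables.

    Attributes
    ----------
    guide_bf_ : pandas.Series
        Mean log2 BF per guide over the permutations in which it was scored.
    gene_bf_ : pandas.Series
        Sum of the gene's guide BFs.
    n_scored_ : pandas.Series
        Number of permutations in which each guide was scored.
    """

    def __init__(
        self,
        n_permutations: int = 100,
        train_fraction: float = 0.60,
        density_floor: float = DENSITY_FLOOR,
        random_state: int | None = None,
    ):
        self.n_permutations = n_permutations
        self.train_fraction = train_fraction
        self.density_floor = density_floor
        self.random_state = random_state

    def fit(self, lfc: pd.Series, genes: pd.Series, refs: ReferenceSets):
        """Fit on per-guide log2 fold changes.

        Parameters
        ----------
        lfc : Series indexed by guide/construct id (one observation each).
        genes : Series mapping the same ids to gene labels.
        refs : gold-standard essential / non-essential gene sets.
        """
        scheme = BootstrapScheme(self.n_permutations, self.train_fraction, None)
        lfc = pd.Series(lfc).astype(float)
        genes = pd.Series(genes).reindex(lfc.index)
        if genes.isna().any():
            raise ValueError("every scored id needs a gene label")

        ess_idx = np.flatnonzero(genes.isin(refs.essential).to_numpy())
        non_idx = np.flatnonzero(genes.isin(refs.non_essential).to_numpy())
        if ess_idx.size < _MIN_REFERENCE_GUIDES or non_idx.size < _MIN_REFERENCE_GUIDES:
            raise ValueError(
                f"reference overlap too small: {ess_idx.size} essential / "
                f"{non_idx.size} non-essential guides (need >= {_MIN_REFERENCE_GUIDES} each)"
            )
        ref_idx = np.concatenate([ess_idx, non_idx])
        other_idx = np.setdiff1d(np.arange(len(lfc)), ref_idx)
        x = lfc.to_numpy()

        rng = np.random.default_rng(self.random_state)
        splits = self._draw_splits(rng, ess_idx, non_idx, scheme)

        bf_sum = np.zeros(len(lfc))
        n_scored = np.zeros(len(lfc), dtype=int)
        for train_e, train_n, test_ref in splits:
            dp = fit_densities(x[train_e], x[train_n], floor=self.density_floor)
            score_idx = np.concatenate([test_ref, other_idx])
            bf_sum[score_idx] += guide_bf(x[score_idx], dp)
            n_scored[score_idx] += 1

        with np.errstate(invalid="ignore"):
            mean_bf = np.where(n_scored > 0, bf_sum / np.maximum(n_scored, 1), np.nan)
        self.guide_bf_ = pd.Series(mean_bf, index=lfc.index, name="guide_bf")
        self.n_scored_ = pd.Series(n_scored, index=lfc.index, name="n_permutations_scored")
        self.gene_bf_ = self.guide_bf_.groupby(genes).sum().rename("gene_bf")
        self.genes_ = genes
        return self

    def _draw_splits(self, rng, ess_idx, non_idx, scheme: BootstrapScheme):
        """Stratified 60/40 train/test splits; every reference guide must land
        in at least one test split across permutations (re-drawn otherwise)."""
        n_e = max(1, round(scheme.train_fraction * ess_idx.size))
        n_n = max(1, round(scheme.train_fraction * non_idx.size))
        full_train = scheme.train_fraction >= 1.0
        for _attempt in range(100):
            splits = []
            tested = set()
            for _ in range(scheme.n_permutations):
                pe = rng.permutation(ess_idx)
                pn = rng.permutation(non_idx)
                if full_train:
                    train_e, train_n = pe, pn
                    test = np.concatenate([ess_idx, non_idx])
                else:
                    train_e, test_e = pe[:n_e], pe[n_e:]
                    train_n, test_n = pn[:n_n], pn[n_n:]
                    test = np.concatenate([test_e, test_n])
                splits.append((train_e, train_n, test))
                tested.update(test.tolist())
            if full_train or tested >= set(np.concatenate([ess_idx, non_idx]).tolist()):
                return splits
        raise RuntimeError("could not cover every reference guide in a test split")

    def result(self) -> BayesFactorTable:
        table = pd.DataFrame(
            {"gene": self.genes_, "guide_bf": self.guide_bf_,
             "n_permutations_scored": self.n_scored_}
        )
        return BayesFactorTable(guide_table=table, gene_bf=self.gene_bf_)

    def predict(self, genes=None, refs: ReferenceSets | None = None, fdr: float = 0.01):
        """Essentiality hit calls at the given FDR (see ``call_hits_at_fdr``)."""
        if refs is None:
            raise ValueError("reference sets are required for FDR hit calling")
        hits, _thr = call_hits_at_fdr(self.result(), refs, fdr)
        idx = self.gene_bf_.index if genes is None else pd.Index(genes)
        return idx.isin(hits)


def guide_level_lfc(
    fc: FoldChangeMatrix, library: GuideLibrary, timepoint: int | None = None,
    replicate: int | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Per-construct lfc observations and gene labels for BF computation.

    Each construct contributes one observation: the replicate-mean lfc at the
    chosen timepoint (default endpoint), or a single replicate's lfc when
    ``replicate`` is given.  For mono-cistronic libraries a construct *is* a
    guide; for multiplexed arrays the construct is the observational unit.
    """
    if replicate is None:
        obs = fc.replicate_mean(timepoint)
    else:
        tp = fc.endpoint() if timepoint is None else timepoint
        obs = fc.column(tp, replicate)
    genes = library.construct_genes().reindex(obs.index)
    return obs, genes


def run_lowfat_bagel(
    fc: FoldChangeMatrix,
    library: GuideLibrary,
    refs: ReferenceSets,
    scheme: BootstrapScheme | None = None,
    timepoint: int | None = None,
) -> BayesFactorTable:
    """End-to-end wrapper: endpoint replicate-mean lfc -> Bayes-factor table."""
    scheme = scheme or BootstrapScheme()
    obs, genes = guide_level_lfc(fc, library, timepoint)
    est = LowFatBagel(
        n_permutations=scheme.n_permutations,
        train_fraction=scheme.train_fraction,
        random_state=scheme.seed,
    ).fit(obs, genes, refs)
    return est.result()


def call_hits_at_fdr(
    bft: BayesFactorTable, refs: ReferenceSets, fdr: float = 0.01
) -> tuple[set[str], float]:
    """Hit set and BF threshold at which reference-gene precision >= 1 - FDR.

    Genes are ranked by BF descending; precision is computed over reference
    genes only (essential = true positive, non-essential = false positive).
    The threshold is the smallest BF at which the running precision still
    meets 1 - fdr; all genes (reference or not) at or above it are hits.
    """
    if not 0.0 < fdr < 1.0:
        raise ValueError("fdr must be in (0, 1)")
    bf = bft.gene_bf.sort_values(ascending=False, kind="stable")
    is_ess = bf.index.isin(refs.essential)
    is_non = bf.index.isin(refs.non_essential)
    ref_mask = is_ess | is_non
    if not ref_mask.any():
        raise ValueError("no reference genes scored")
    tp = np.cumsum(is_ess)
    fp = np.cumsum(is_non)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(ref_mask.cumsum() > 0, tp / np.maximum(tp + fp, 1), 0.0)
    ok = np.flatnonzero(ref_mask & (precision >= 1.0 - fdr))
    if ok.size == 0:
        logger.warning("precision never reaches %.3f: empty hit set", 1.0 - fdr)
        return set(), float("inf")
    threshold = float(bf.iloc[ok[-1]])
    hits = set(bf.index[bf.to_numpy() >= threshold])
    return hits, threshold
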