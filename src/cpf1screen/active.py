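"""FPR-controlled active-construct calling.

A depletion threshold is placed on the log2 fold-change distribution of
non-essential-targeting constructs so that a chosen fraction (the false
positive rate) of them fall below it; the fraction of essential-targeting
constructs below the same threshold is the library's "active construct"
percentage — a measure of how many vectors actually cut.

Thresholds are computed per replicate per timepoint; the summary reports the
mean +/- s.d. of the active fraction across replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import FoldChangeMatrix, GuideLibrary, ReferenceSets


def fpr_threshold(lfc_nonessential, fpr: float) -> float:
    """Lower-tail empirical quantile: exactly floor(fpr*n) values fall strictly below.

    The threshold is the (k+1)-th smallest value with k = floor(fpr*n); calls
    use a strict ``<`` comparison, so ties at the threshold count as
    non-active (conservative: empirical FPR stays <= nominal).
    """
    x = np.asarray(lfc_nonessential, dtype=float)
    if x.size == 0:
        raise ValueError("non-essential lfc list is empty")
    if not 0.0 < fpr < 1.0:
        raise ValueError("fpr must be in (0, 1)")
    k = math.floor(fpr * x.size)
    if k < 1:
        raise ValueError(
            f"fpr*n = {fpr * x.size:.3g} < 1: threshold undefined for n={x.size}"
        )
    return float(np.sort(x)[k])  # (k+1)-th order statistic


@dataclass
class ActiveCallResult:
    fpr: float
    per_sample: pd.DataFrame  # timepoint, replicate, threshold_lfc, n_essential, n_active, active_fraction
    summary: pd.DataFrame  # timepoint, mean, sd across replicates

    def endpoint_mean(self) -> float:
        return float(self.summary.loc[self.summary["timepoint"].idxmax(), "mean"])


def active_fraction(
    fc: FoldChangeMatrix,
    library: GuideLibrary,
    refs: ReferenceSets,
    fpr: float = 0.05,
) -> ActiveCallResult:
    """Per replicate and timepoint: fraction of essential constructs below the FPR threshold."""
    genes = library.construct_genes().reindex(fc.lfc.index)
    ess_mask = genes.isin(refs.essential).to_numpy()
    non_mask = genes.isin(refs.non_essential).to_numpy()
    if not ess_mask.any():
        raise ValueError("no essential-targeting constructs in fold-change matrix")
    if not non_mask.any():
        raise ValueError("no non-essential-targeting constructs in fold-change matrix")

    rows = []
    for s in fc.samples:
        col = fc.lfc[s.name].to_numpy()
        thr = fpr_threshold(col[non_mask], fpr)
        ess = col[ess_mask]
        n_active = int((ess < thr).sum())
        rows.append(
            (s.timepoint, s.replicate, thr, ess.size, n_active, n_active / ess.size)
        )
    per_sample = pd.DataFrame(
        rows,
        columns=[
            "timepoint", "replicate", "threshold_lfc",
            "n_essential", "n_active", "active_fraction",
        ],
    ).sort_values(["timepoint", "replicate"], ignore_index=True)
    summary = (
        per_sample.groupby("timepoint")["active_fraction"]
        .agg(mean="mean", sd="std")
        .reset_index()
    )
    return ActiveCallResult(fpr=fpr, per_sample=per_sample, summary=summary)
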