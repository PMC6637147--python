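"""Count normalization and log2 fold change against the reference sample.

Each sample column is scaled to a common total read depth, a pseudocount is
added, and each non-reference sample is compared against the reference sample
of its own replicate.  Replicate averaging happens only at reporting time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import CountMatrix, FoldChangeMatrix

DEFAULT_SCALE = 10_000_000.0
DEFAULT_PSEUDOCOUNT = 0.5


def normalize_counts(
    cm: CountMatrix,
    scale: float = DEFAULT_SCALE,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Scale every sample column to ``scale`` total reads, then add ``pseudocount``."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    totals = cm.counts.sum(axis=0)
    zero = [c for c, t in totals.items() if t == 0]
    if zero:
        raise ValueError(f"cannot normalize all-zero sample columns: {zero}")
    return cm.counts / totals * scale + pseudocount


def log2_fold_change(
    cm: CountMatrix,
    scale: float = DEFAULT_SCALE,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> FoldChangeMatrix:
    """lfc = log2(norm(sample)) - log2(norm(reference of the same replicate))."""
    norm = np.log2(normalize_counts(cm, scale, pseudocount))
    cols = {}
    samples = []
    for s in cm.samples:
        if s.is_reference:
            continue
        try:
            ref = cm.reference_sample(s.replicate)
        except KeyError as exc:
            raise ValueError(f"missing reference sample for replicate {s.replicate}") from exc
        cols[s.name] = norm[s.name] - norm[ref.name]
        samples.append(s)
    return FoldChangeMatrix(lfc=pd.DataFrame(cols, index=cm.counts.index), samples=samples)


def write_foldchange(fc: FoldChangeMatrix, path) -> None:
    out = fc.lfc.copy()
    out.index.name = "construct_id"
    out.to_csv(path, sep="\t", float_format="%.6f")


def read_foldchange(path) -> FoldChangeMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="construct_id")
    return FoldChangeMatrix(lfc=df)
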