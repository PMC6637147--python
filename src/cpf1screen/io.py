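"""Readers, writers and summaries for library / count / gene-set tables.

File dialect: tab-separated, UTF-8, one mandatory header row, ``#`` comment
lines skipped.  Ragged multiplexed arrays (e.g. 3-guide constructs in a
4-guide library) are stored with trailing empty cells, never placeholder
sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .types import (
    Construct,
    CountMatrix,
    GuideLibrary,
    NucleaseMode,
    NON_TARGETING,
    ReferenceSets,
    SampleLabel,
)

logger = logging.getLogger(__name__)


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#", dtype=str, keep_default_na=False
    )


def read_library(path: str | Path, mode: NucleaseMode | str) -> GuideLibrary:
    """Read a guide library TSV (columns construct_id, gene, guide_1..guide_k).

    Raises ``ValueError`` naming the offending row/id on duplicate construct
    ids, non-ACGT characters, or guides of the wrong length.
    """
    mode = NucleaseMode(mode)
    df = _read_tsv(path)
    required = ["construct_id", "gene"]
    guide_cols = [c for c in df.columns if c.startswith("guide_")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if not guide_cols:
        raise ValueError(f"{path}: no guide_<k> columns found")
    if len(guide_cols) > 7:
        raise ValueError(f"{path}: {len(guide_cols)} guide columns (maximum 7)")

    constructs: list[Construct] = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        guides = [rec[c].strip().upper() for c in guide_cols]
        # trailing empties permitted for ragged arrays; internal gaps are not
        while guides and guides[-1] == "":
            guides.pop()
        if "" in guides:
            raise ValueError(
                f"{path} row {row_number}: empty guide cell before a filled one"
            )
        try:
            constructs.append(
                Construct(rec["construct_id"].strip(), rec["gene"].strip(), tuple(guides))
            )
        except ValueError as exc:
            raise ValueError(f"{path} row {row_number}: {exc}") from exc
    return GuideLibrary(constructs, mode)


def write_library(lib: GuideLibrary, path: str | Path) -> None:
    """Write a library in the canonical TSV dialect (round-trips byte-identically)."""
    k = max((len(c.guides) for c in lib.constructs), default=1)
    header = ["construct_id", "gene"] + [f"guide_{i}" for i in range(1, k + 1)]
    lines = ["\t".join(header)]
    for c in lib.constructs:
        guides = list(c.guides) + [""] * (k - len(c.guides))
        lines.append("\t".join([c.construct_id, c.gene] + guides))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass(frozen=True)
class LibrarySummary:
    n_constructs: int
    n_guides: int
    n_genes: int
    n_nontargeting: int
    guides_per_construct_histogram: dict[int, int]


def summarize_library(lib: GuideLibrary) -> LibrarySummary:
    """Construct/guide/gene totals; non-targeting controls excluded from n_genes."""
    hist: dict[int, int] = {}
    genes: set[str] = set()
    n_guides = 0
    n_nt = 0
    for c in lib.constructs:
        k = len(c.guides)
        hist[k] = hist.get(k, 0) + 1
        n_guides += k
        if c.is_nontargeting:
            n_nt += 1
        else:
            genes.add(c.gene)
    return LibrarySummary(
        n_constructs=len(lib.constructs),
        n_guides=n_guides,
        n_genes=len(genes),
        n_nontargeting=n_nt,
        guides_per_construct_histogram=dict(sorted(hist.items())),
    )


def read_counts(path: str | Path, library: GuideLibrary) -> CountMatrix:
    """Read a counts TSV (first column construct_id, remaining sample labels).

    Constructs are aligned to library order; constructs present in the counts
    file but absent from the library are a hard error, missing library
    constructs are reported and dropped.
    """
    df = _read_tsv(path)
    first = df.columns[0]
    if first != "construct_id":
        raise ValueError(f"{path}: first column must be 'construct_id', got {first!r}")
    samples = [SampleLabel.parse(c) for c in df.columns[1:]]
    df = df.set_index("construct_id")

    lib_ids = library.construct_ids
    extra = [i for i in df.index if i not in set(lib_ids)]
    if extra:
        raise ValueError(f"{path}: constructs not in library: {extra[:5]}")
    missing = [i for i in lib_ids if i not in set(df.index)]
    if missing:
        logger.warning("%s: %d library constructs missing from counts, e.g. %s",
                       path, len(missing), missing[:5])
    order = [i for i in lib_ids if i in set(df.index)]

    try:
        counts = df.loc[order].astype("int64")
    except ValueError as exc:
        raise ValueError(f"{path}: counts must be integers ({exc})") from exc
    if (counts.to_numpy() < 0).any():
        bad = counts.index[(counts < 0).any(axis=1)][0]
        raise ValueError(f"{path}: negative count for construct {bad!r}")
    zero_cols = [c for c in counts.columns if counts[c].sum() == 0]
    if zero_cols:
        logger.warning("%s: all-zero count columns: %s", path, zero_cols)
    return CountMatrix(counts=counts, samples=samples)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    out = cm.counts.copy()
    out.index.name = "construct_id"
    out.to_csv(path, sep="\t")


def read_gene_list(path: str | Path) -> set[str]:
    """One gene symbol per line; blank lines and '#' comments skipped."""
    genes: set[str] = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.add(line)
    return genes


def read_reference_sets(essential_path: str | Path, nonessential_path: str | Path) -> ReferenceSets:
    return ReferenceSets(
        essential=frozenset(read_gene_list(essential_path)),
        non_essential=frozenset(read_gene_list(nonessential_path)),
    )


def write_gene_list(genes, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n", encoding="utf-8")
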