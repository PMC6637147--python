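"""Core domain types for pooled CRISPR screen data.

A screen library is a collection of constructs; each construct carries one or
more 20-nt protospacers targeting a single gene (or a non-targeting control).
Mono-cistronic libraries (SpCas9 or AsCpf1) have one guide per construct;
multiplexed AsCpf1 libraries encode a whole crRNA array — up to seven guides
processed by Cpf1 itself — on a single vector.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

#: Gene label reserved for non-targeting control constructs.  Constructs with
#: this label are kept in construct-level output but excluded from gene-level
#: statistics.
NON_TARGETING = "NonTargeting"

GUIDE_LENGTH = 20
MAX_GUIDES_PER_ARRAY = 7

_GUIDE_RE = re.compile(r"^[ACGT]{20}$")


class NucleaseMode(str, Enum):
    """Library architecture: one guide per vector, or a Cpf1 guide array."""

    CAS9_MONO = "cas9_mono"
    CPF1_MONO = "cpf1_mono"
    CPF1_MULTI = "cpf1_multi"

    @property
    def is_mono(self) -> bool:
        return self is not NucleaseMode.CPF1_MULTI


@dataclass(frozen=True)
class Construct:
    """One library vector: a gene label and its ordered protospacers.

    Guide order is preserved because the cistron position within a Cpf1
    array is meaningful downstream (oligo assembly, per-position QC).
    """

    construct_id: str
    gene: str
    guides: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.construct_id:
            raise ValueError("construct_id must be non-empty")
        if not self.gene:
            raise ValueError(f"construct {self.construct_id!r}: gene label must be non-empty")
        if not self.guides:
            raise ValueError(f"construct {self.construct_id!r}: needs at least one guide")
        for g in self.guides:
            if len(g) != GUIDE_LENGTH:
                raise ValueError(
                    f"construct {self.construct_id!r}: guide {g!r} has length "
                    f"{len(g)}, expected {GUIDE_LENGTH}"
                )
            if not _GUIDE_RE.match(g):
                raise ValueError(
                    f"construct {self.construct_id!r}: guide {g!r} contains "
                    "characters outside A/C/G/T"
                )

    @property
    def is_nontargeting(self) -> bool:
        return self.gene == NON_TARGETING


@dataclass
class GuideLibrary:
    """A validated guide library with a declared nuclease mode."""

    constructs: list[Construct]
    nuclease_mode: NucleaseMode

    def __post_init__(self) -> None:
        self.nuclease_mode = NucleaseMode(self.nuclease_mode)
        seen: set[str] = set()
        for c in self.constructs:
            if c.construct_id in seen:
                raise ValueError(f"duplicate construct_id {c.construct_id!r}")
            seen.add(c.construct_id)
            n = len(c.guides)
            if self.nuclease_mode.is_mono and n != 1:
                raise ValueError(
                    f"construct {c.construct_id!r}: {n} guides in mono-cistronic "
                    f"mode {self.nuclease_mode.value!r} (exactly 1 required)"
                )
            if not self.nuclease_mode.is_mono and not 1 <= n <= MAX_GUIDES_PER_ARRAY:
                raise ValueError(
                    f"construct {c.construct_id!r}: {n} guides; multiplexed arrays "
                    f"carry 1-{MAX_GUIDES_PER_ARRAY} guides"
                )

    def __len__(self) -> int:
        return len(self.constructs)

    def __iter__(self):
        return iter(self.constructs)

    @property
    def construct_ids(self) -> list[str]:
        return [c.construct_id for c in self.constructs]

    def construct_genes(self) -> pd.Series:
        """Gene label per construct, indexed by construct_id."""
        return pd.Series(
            {c.construct_id: c.gene for c in self.constructs}, name="gene"
        ).reindex(self.construct_ids)

    def guide_table(self) -> pd.DataFrame:
        """One row per guide: guide_id, construct_id, gene, cistron, sequence.

        Guide ids are ``<construct_id>_g<cistron>`` with cistron numbered
        from 1 in array order.
        """
        rows = []
        for c in self.constructs:
            for i, g in enumerate(c.guides, start=1):
                rows.append((f"{c.construct_id}_g{i}", c.construct_id, c.gene, i, g))
        return pd.DataFrame(
            rows, columns=["guide_id", "construct_id", "gene", "cistron", "sequence"]
        ).set_index("guide_id")


@dataclass(frozen=True)
class ReferenceSets:
    """Gold-standard essential / non-essential gene sets.

    The benchmark sets used throughout are 342 core-essential and 345
    non-essential genes; their prevalence 342/687 = 0.498 is the null
    precision-recall baseline.
    """

    essential: frozenset[str]
    non_essential: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "essential", frozenset(self.essential))
        object.__setattr__(self, "non_essential", frozenset(self.non_essential))
        if not self.essential or not self.non_essential:
            raise ValueError("both reference sets must be non-empty")
        overlap = self.essential & self.non_essential
        if overlap:
            raise ValueError(f"reference sets overlap: {sorted(overlap)[:5]}")

    @property
    def all_genes(self) -> frozenset[str]:
        return self.essential | self.non_essential

    @property
    def prevalence(self) -> float:
        return len(self.essential) / (len(self.essential) + len(self.non_essential))


_SAMPLE_RE = re.compile(r"^T(?P<tp>\d+)_(?P<ref>ref_)?R(?P<rep>\d+)$")


@dataclass(frozen=True, order=True)
class SampleLabel:
    """A screen sample: timepoint ordinal, replicate ordinal, reference flag."""

    timepoint: int
    replicate: int
    is_reference: bool = False

    @property
    def name(self) -> str:
        ref = "ref_" if self.is_reference else ""
        return f"T{self.timepoint}_{ref}R{self.replicate}"

    @classmethod
    def parse(cls, label: str) -> "SampleLabel":
        m = _SAMPLE_RE.match(label)
        if m is None:
            raise ValueError(
                f"sample label {label!r} does not match 'T<k>_R<j>' or 'T<k>_ref_R<j>'"
            )
        return cls(
            timepoint=int(m.group("tp")),
            replicate=int(m.group("rep")),
            is_reference=m.group("ref") is not None,
        )


@dataclass
class CountMatrix:
    """Constructs x samples read counts with exactly one reference per replicate."""

    counts: pd.DataFrame  # index: construct_id, columns: sample label strings
    samples: list[SampleLabel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.samples:
            self.samples = [SampleLabel.parse(c) for c in self.counts.columns]
        if list(self.counts.columns) != [s.name for s in self.samples]:
            raise ValueError("count columns do not match sample labels")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts are not allowed")
        reps = {s.replicate for s in self.samples}
        for rep in reps:
            n_ref = sum(1 for s in self.samples if s.replicate == rep and s.is_reference)
            if n_ref != 1:
                raise ValueError(
                    f"replicate {rep} has {n_ref} reference samples (exactly 1 required)"
                )

    @property
    def replicates(self) -> list[int]:
        return sorted({s.replicate for s in self.samples})

    @property
    def timepoints(self) -> list[int]:
        return sorted({s.timepoint for s in self.samples if not s.is_reference})

    def reference_sample(self, replicate: int) -> SampleLabel:
        for s in self.samples:
            if s.replicate == replicate and s.is_reference:
                return s
        raise KeyError(f"no reference sample for replicate {replicate}")


@dataclass
class FoldChangeMatrix:
    """Constructs x non-reference samples log2 fold changes vs reference."""

    lfc: pd.DataFrame  # index: construct_id, columns: sample label strings
    samples: list[SampleLabel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.samples:
            self.samples = [SampleLabel.parse(c) for c in self.lfc.columns]
        if any(s.is_reference for s in self.samples):
            raise ValueError("fold-change matrix must not contain reference samples")
        import numpy as np

        if not np.isfinite(self.lfc.to_numpy()).all():
            raise ValueError("fold changes must be finite")

    @property
    def replicates(self) -> list[int]:
        return sorted({s.replicate for s in self.samples})

    @property
    def timepoints(self) -> list[int]:
        return sorted({s.timepoint for s in self.samples})

    def endpoint(self) -> int:
        return max(self.timepoints)

    def column(self, timepoint: int, replicate: int) -> pd.Series:
        return self.lfc[SampleLabel(timepoint, replicate).name]

    def replicate_mean(self, timepoint: int | None = None) -> pd.Series:
        """Mean lfc across replicates at one timepoint (default: endpoint)."""
        tp = self.endpoint() if timepoint is None else timepoint
        cols = [s.name for s in self.samples if s.timepoint == tp]
        if not cols:
            raise KeyError(f"no samples at timepoint {tp}")
        return self.lfc[cols].mean(axis=1)
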