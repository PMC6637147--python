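"""Multiplexed AsCpf1 library design: TTTV PAM scanning, cloning filters,
mismatch-tolerant off-target counting, guide ranking and crRNA array assembly.

AsCpf1 requires a TTTV PAM (V = A/C/G) 5' of a 20-nt protospacer.  The
designer scans both genome strands for PAM sites, removes protospacers with
homopolymer runs (a T-run acts as a Pol III terminator) or BsmBI sites
(which would break Golden-Gate cloning), counts near-identical genomic
sites under a Hamming mismatch tolerance and classifies them by annotation
(exonic > intronic > intergenic precedence), ranks the survivors and packs
the top guides per gene into a direct-repeat-separated crRNA array.

The off-target engine is an exhaustive PAM-anchored Hamming scan — bit-exact
and dependency-free at the toy-genome scales this module targets; read-mapper
parity is out of scope.

Coordinates are 0-based, half-open, reported on the forward strand; reverse
strand candidates carry a strand flag with PAM coordinates on the forward
axis, and protospacers are always given in PAM-strand orientation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .scoring import ScoreTable, score_guide

PAM_RE = re.compile(r"(?=(TTT[ACG]))")
PROTOSPACER_LEN = 20
PAM_LEN = 4
BSMBI_SITE = "CGTCTC"
BSMBI_SITE_RC = "GAGACG"
MAX_ARRAY_GUIDES = 7
#: AsCpf1 crRNA direct repeat (19 nt); configurable everywhere it is used.
DEFAULT_DIRECT_REPEAT = "AATTTCTACTCTTGTAGAT"
#: Cut-site approximation: staggered Cpf1 cut ~18 nt into the protospacer.
DEFAULT_CUT_OFFSET = 18

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_genome(path: str | Path) -> dict[str, str]:
    """FASTA -> {chrom: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


@dataclass
class DesignCandidate:
    chrom: str
    pam_start: int  # 0-based forward-axis start of the 4-nt PAM
    strand: str  # '+' or '-'
    pam: str  # PAM-strand orientation
    protospacer: str  # 20-mer, PAM-strand orientation
    filters_failed: set[str] = field(default_factory=set)
    offtargets: dict[str, int] = field(default_factory=dict)
    sequence_score: float = 0.0
    target_transcripts: int = 0
    distance_to_first_exon: int = 0
    gene: str | None = None

    @property
    def protospacer_interval(self) -> tuple[int, int]:
        """Forward-axis half-open interval covered by the protospacer."""
        if self.strand == "+":
            start = self.pam_start + PAM_LEN
        else:
            start = self.pam_start - PROTOSPACER_LEN
        return start, start + PROTOSPACER_LEN

    def cut_site(self, offset: int = DEFAULT_CUT_OFFSET) -> int:
        """Approximate forward-axis cut position, ``offset`` nt into the protospacer."""
        if self.strand == "+":
            return self.pam_start + PAM_LEN + offset
        return self.pam_start - offset

    @property
    def site_key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pam_start, self.strand)


def _scan_strand(chrom: str, seq: str, strand: str, length: int) -> list[DesignCandidate]:
    out = []
    for m in PAM_RE.finditer(seq):
        i = m.start()
        if i + PAM_LEN + PROTOSPACER_LEN > len(seq):
            continue
        proto = seq[i + PAM_LEN : i + PAM_LEN + PROTOSPACER_LEN]
        if "N" in proto:
            continue
        pam_start = i if strand == "+" else length - i - PAM_LEN
        out.append(
            DesignCandidate(chrom=chrom, pam_start=pam_start, strand=strand,
                            pam=m.group(1), protospacer=proto)
        )
    return out


def scan_pams(genome: dict[str, str] | str | Path) -> list[DesignCandidate]:
    """Every TTTV PAM on either strand with a full N-free 20-mer protospacer 3' of it."""
    if not isinstance(genome, dict):
        genome = read_genome(genome)
    cands: list[DesignCandidate] = []
    for chrom, seq in genome.items():
        seq = seq.upper()
        cands.extend(_scan_strand(chrom, seq, "+", len(seq)))
        cands.extend(_scan_strand(chrom, revcomp(seq), "-", len(seq)))
    return cands


def _max_run(seq: str, base: str) -> int:
    best = run = 0
    for ch in seq:
        run = run + 1 if ch == base else 0
        best = max(best, run)
    return best


def filter_candidates(
    cands: list[DesignCandidate],
    t_run: int = 4,
    other_run: int = 5,
) -> list[DesignCandidate]:
    """Populate ``filters_failed`` (homopolymer, bsmbi) in place; returns the list.

    A T-run of ``t_run`` or longer (Pol III terminator) or any other base run
    of ``other_run`` or longer fails ``homopolymer``; a BsmBI recognition
    site (CGTCTC) on either strand of the protospacer fails ``bsmbi``.
    """
    for c in cands:
        failed = set()
        if _max_run(c.protospacer, "T") >= t_run or any(
            _max_run(c.protospacer, b) >= other_run for b in "ACG"
        ):
            failed.add("homopolymer")
        if BSMBI_SITE in c.protospacer or BSMBI_SITE_RC in c.protospacer:
            failed.add("bsmbi")
        c.filters_failed = failed
    return cands


@dataclass(frozen=True)
class OffTargetPolicy:
    """Mismatch tolerance and exclusion rules for off-target counting.

    ``benchmark``: at most 1 mismatch within the PAM-adjacent 18 nt counts
    as an off-target hit; guides with more than 2 total predicted
    off-targets are excluded.  ``minihuman``: at most 1 mismatch anywhere in
    the 20-mer outside the PAM; any exonic or intronic off-target excludes
    the guide and survivors are ranked by intergenic hit count (ascending).
    """

    mode: str = "minihuman"

    def __post_init__(self) -> None:
        if self.mode not in ("benchmark", "minihuman"):
            raise ValueError(f"unknown off-target policy {self.mode!r}")

    @property
    def window(self) -> int:
        return 18 if self.mode == "benchmark" else PROTOSPACER_LEN

    @property
    def max_mismatches(self) -> int:
        return 1

    def excludes(self, cand: DesignCandidate) -> bool:
        ot = cand.offtargets
        if self.mode == "benchmark":
            return sum(ot.values()) > 2
        return ot.get("exonic", 0) + ot.get("intronic", 0) > 0


def classify_position(chrom: str, pos: int, annotation: pd.DataFrame | None) -> str:
    """Annotation class at a position; exonic beats intronic, default intergenic."""
    if annotation is None:
        return "intergenic"
    rows = annotation[
        (annotation["chrom"] == chrom)
        & (annotation["start"] <= pos)
        & (pos < annotation["end"])
    ]
    if (rows["class"] == "exonic").any():
        return "exonic"
    if (rows["class"] == "intronic").any():
        return "intronic"
    return "intergenic"


def _hamming_within(a: str, b: str, window: int, limit: int) -> bool:
    mm = 0
    for x, y in zip(a[:window], b[:window]):
        if x != y:
            mm += 1
            if mm > limit:
                return False
    return True


def count_offtargets(
    cand: DesignCandidate,
    genome: dict[str, str] | str | Path,
    annotation: pd.DataFrame | None,
    policy: OffTargetPolicy,
    sites: list[DesignCandidate] | None = None,
) -> dict[str, int]:
    """Exhaustive PAM-anchored scan for near-identical genomic sites.

    Every TTTV-PAM site whose protospacer is within the policy's mismatch
    tolerance of the candidate's counts as a hit, classified by the midpoint
    of its protospacer; the on-target locus itself is excluded.  Pass a
    precomputed ``sites`` list (from ``scan_pams``) to amortize the scan.
    """
    if sites is None:
        sites = scan_pams(genome)
    counts = {"exonic": 0, "intronic": 0, "intergenic": 0}
    for site in sites:
        if site.site_key == cand.site_key:
            continue
        if not _hamming_within(
            cand.protospacer, site.protospacer, policy.window, policy.max_mismatches
        ):
            continue
        lo, hi = site.protospacer_interval
        counts[classify_position(site.chrom, (lo + hi) // 2, annotation)] += 1
    cand.offtargets = counts
    return counts


def select_guides(
    cands: list[DesignCandidate],
    table: ScoreTable | None,
    k: int,
    policy: OffTargetPolicy,
) -> list[DesignCandidate]:
    """Top-k guides after filter/off-target exclusion.

    Ranking is lexicographic: most transcripts targeted, fewest intergenic
    off-targets, highest sequence score, closest to the first exon.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    survivors = []
    for c in cands:
        if c.filters_failed or policy.excludes(c):
            continue
        if table is not None:
            c.sequence_score = score_guide(c.protospacer, table).score
        survivors.append(c)
    survivors.sort(
        key=lambda c: (
            -c.target_transcripts,
            c.offtargets.get("intergenic", 0),
            -c.sequence_score,
            c.distance_to_first_exon,
        )
    )
    return survivors[:k]


@dataclass
class GuideArray:
    """An assembled multiplexed crRNA array: DR-guide repeats for one gene."""

    construct_id: str
    gene: str
    guides: tuple[str, ...]
    direct_repeat: str
    oligo: str


def build_array(gene: str, guides, direct_repeat: str) -> GuideArray:
    """Assemble DR+g1+DR+g2+... for 1-7 guides (oligo-synthesis limit)."""
    guides = tuple(guides)
    if not guides:
        raise ValueError("empty guide list")
    if len(guides) > MAX_ARRAY_GUIDES:
        raise ValueError(f"{len(guides)} guides exceeds the {MAX_ARRAY_GUIDES}-guide synthesis limit")
    oligo = "".join(direct_repeat + g for g in guides)
    return GuideArray(
        construct_id=f"{gene}_array", gene=gene, guides=guides,
        direct_repeat=direct_repeat, oligo=oligo,
    )


def combinatorial_size(
    n_genes: int, perturbagens_per_gene: int, arity: int = 2,
    mode: str = "multiplexed",
) -> int:
    """Vector count to probe all two-gene combinations (ordered pairs, self-pairs included).

    ``mono_pairwise`` (one perturbagen per vector slot, as for Cas9/RNAi
    pairs): n^2 * p^2.  ``multiplexed`` (one array covers a gene's whole
    perturbagen set): n^2.
    """
    if arity != 2:
        raise ValueError("only pairwise (arity 2) combinatorial sizing is supported")
    if mode == "mono_pairwise":
        return n_genes**2 * perturbagens_per_gene**2
    if mode == "multiplexed":
        return n_genes**2
    raise ValueError(f"unknown mode {mode!r}")


def array_span(
    cands: list[DesignCandidate], cut_offset: int = DEFAULT_CUT_OFFSET
) -> int | None:
    """Genomic span (bases) between extreme approximate cut sites.

    Returns None (undefined) when guides sit on different chromosomes.
    """
    if not cands:
        raise ValueError("no guides")
    if len({c.chrom for c in cands}) > 1:
        return None
    cuts = [c.cut_site(cut_offset) for c in cands]
    return max(cuts) - min(cuts)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Interval table: chrom, start, end, class, gene, transcript_count, first_exon_start."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"chrom", "start", "end", "class", "gene"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation missing columns {sorted(missing)}")
    return df


def design_library(
    genome: dict[str, str] | str | Path,
    annotation: pd.DataFrame,
    table: ScoreTable | None = None,
    guides_per_gene: int = 4,
    policy: OffTargetPolicy | None = None,
    direct_repeat: str = DEFAULT_DIRECT_REPEAT,
    min_guides: int = 3,
) -> tuple[list[GuideArray], pd.DataFrame]:
    """End-to-end designer on a genome + exon annotation.

    Candidates whose protospacer midpoint falls in a gene's exonic interval
    are assigned to that gene, filtered, off-target-counted, ranked and
    packed into arrays of up to ``guides_per_gene`` guides (genes with fewer
    than ``min_guides`` survivors go to the dropout manifest).  Returns the
    arrays plus a manifest DataFrame (gene, n_candidates, n_selected, status).
    """
    if not isinstance(genome, dict):
        genome = read_genome(genome)
    policy = policy or OffTargetPolicy("minihuman")
    sites = scan_pams(genome)
    filter_candidates(sites)

    exons = annotation[annotation["class"] == "exonic"]
    per_gene: dict[str, list[DesignCandidate]] = {g: [] for g in exons["gene"].unique()}
    for c in sites:
        lo, hi = c.protospacer_interval
        mid = (lo + hi) // 2
        rows = exons[
            (exons["chrom"] == c.chrom) & (exons["start"] <= mid) & (mid < exons["end"])
        ]
        if rows.empty:
            continue
        row = rows.iloc[0]
        c.gene = row["gene"]
        c.target_transcripts = int(row.get("transcript_count", 1))
        first_exon = int(row.get("first_exon_start", row["start"]))
        c.distance_to_first_exon = abs(c.cut_site() - first_exon)
        per_gene[c.gene].append(c)

    arrays: list[GuideArray] = []
    manifest_rows = []
    for gene, cands in per_gene.items():
        for c in cands:
            count_offtargets(c, genome, annotation, policy, sites=sites)
        picked = select_guides(cands, table, guides_per_gene, policy)
        if len(picked) >= min_guides:
            arrays.append(build_array(gene, [c.protospacer for c in picked], direct_repeat))
            status = "ok"
        else:
            status = "dropout"
        manifest_rows.append((gene, len(cands), len(picked), status))
    manifest = pd.DataFrame(
        manifest_rows, columns=["gene", "n_candidates", "n_selected", "status"]
    ).sort_values("gene", ignore_index=True)
    return arrays, manifest


def candidates_to_frame(cands: list[DesignCandidate]) -> pd.DataFrame:
    """BED-compatible candidate table (chrom, start, end, strand, ...)."""
    rows = []
    for c in cands:
        lo, hi = c.protospacer_interval
        rows.append(
            (c.chrom, lo, hi, c.strand, c.pam_start, c.pam, c.protospacer,
             ",".join(sorted(c.filters_failed)) or ".",
             c.offtargets.get("exonic", 0), c.offtargets.get("intronic", 0),
             c.offtargets.get("intergenic", 0), c.sequence_score, c.gene or ".")
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "strand", "pam_start", "pam", "protospacer",
                 "filters_failed", "ot_exonic", "ot_intronic", "ot_intergenic",
                 "sequence_score", "gene"],
    )
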