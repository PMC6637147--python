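"""TTTV PAM scanning, cloning filters, off-target counting, ranking, assembly."""

import numpy as np
import pandas as pd
import pytest

from cpf1screen import (
    DesignCandidate,
    OffTargetPolicy,
    array_span,
    build_array,
    combinatorial_size,
    count_offtargets,
    design_library,
    filter_candidates,
    scan_pams,
    select_guides,
)
from cpf1screen.design import revcomp


def brute_force_scan(genome: dict[str, str]):
    """Independent oracle: positional scan for TTTV + 20-mer on both strands."""
    hits = set()
    for chrom, seq in genome.items():
        seq = seq.upper()
        n = len(seq)
        for i in range(n - 23):
            pam = seq[i : i + 4]
            proto = seq[i + 4 : i + 24]
            if pam[:3] == "TTT" and pam[3] in "ACG" and "N" not in proto:
                hits.add((chrom, i, "+", proto))
        rc = revcomp(seq)
        for i in range(n - 23):
            pam = rc[i : i + 4]
            proto = rc[i + 4 : i + 24]
            if pam[:3] == "TTT" and pam[3] in "ACG" and "N" not in proto:
                hits.add((chrom, n - i - 4, "-", proto))
    return hits


def as_set(cands):
    return {(c.chrom, c.pam_start, c.strand, c.protospacer) for c in cands}


def test_scan_finds_the_single_hand_checked_candidate():
    cands = scan_pams({"chr1": "TTTACCCCGGGGAAAATTTTCCCCG"})
    assert len(cands) == 1
    c = cands[0]
    assert (c.chrom, c.pam_start, c.strand, c.pam) == ("chr1", 0, "+", "TTTA")
    assert c.protospacer == "CCCCGGGGAAAATTTTCCCC"


def test_tttt_is_not_a_valid_pam():
    # the T run itself yields no PAM (V excludes T); only the TTTA at the
    # run's end, one base downstream, is valid
    cands = scan_pams({"chr1": "TTTT" + "ACGC" * 6})
    assert all(c.pam != "TTTT" for c in cands)
    assert [c.pam_start for c in cands if c.strand == "+"] == [1]


def test_short_sequences_yield_no_candidates():
    assert scan_pams({"chr1": "TTTACGT"}) == []


def test_candidates_overlapping_n_are_dropped():
    assert scan_pams({"chr1": "TTTA" + "ACGC" * 4 + "NACG"}) == []


def test_strand_symmetry_under_reverse_complement():
    rng = np.random.default_rng(8)
    seq = "".join(rng.choice(list("ACGT"), size=500))
    fwd = scan_pams({"c": seq})
    rev = scan_pams({"c": revcomp(seq)})
    assert len(fwd) == len(rev)
    assert sorted(c.protospacer for c in fwd) == sorted(c.protospacer for c in rev)


def test_scan_matches_brute_force_on_random_sequence():
    rng = np.random.default_rng(21)
    genome = {"c1": "".join(rng.choice(list("ACGTN"), size=2000, p=[0.24] * 4 + [0.04]))}
    assert as_set(scan_pams(genome)) == brute_force_scan(genome)


def cand(proto, chrom="chr1", pam_start=0, strand="+", **kw):
    return DesignCandidate(chrom=chrom, pam_start=pam_start, strand=strand,
                           pam="TTTA", protospacer=proto, **kw)


@pytest.mark.parametrize(
    "proto,expected",
    [
        ("ACGTTTTACGACGACGACGA", {"homopolymer"}),  # T-run of 4
        ("AAAAACGTACGTACGTACGT", {"homopolymer"}),  # A-run of 5
        ("AAAACGTACGTACGTACGTA", set()),  # A-run of 4 is fine
        ("ACGCGTCTCGTACGTACGTA", {"bsmbi"}),
        ("ACGGAGACGGTACGTACGTA", {"bsmbi"}),  # reverse complement of the site
        ("ACGTACGTACGTACGTACGT", set()),
    ],
)
def test_cloning_filters(proto, expected):
    c = cand(proto)
    filter_candidates([c])
    assert c.filters_failed == expected


PROTO = "ACGGATCAGCTGAGCTAGGA"  # no T-runs, no BsmBI site, no AAA on either strand
SPACER = "GCGTGCGTGC"


def planted_genome(dup_proto, dup=True):
    seq = "GCGTGCGT" + "TTTA" + PROTO + SPACER
    if dup:
        seq += "TTTA" + dup_proto + SPACER
    return {"chr1": seq + "GCGTGCGT"}


def mutate(s, positions, base="C"):
    out = list(s)
    for p in positions:
        out[p] = "G" if s[p] == base else base
    return "".join(out)


def test_planted_exact_duplicate_counts_as_one_offtarget():
    genome = planted_genome(PROTO)
    cands = scan_pams(genome)
    target = next(c for c in cands if c.pam_start == 8)
    counts = count_offtargets(target, genome, None, OffTargetPolicy("minihuman"))
    assert counts == {"exonic": 0, "intronic": 0, "intergenic": 1}


def test_two_mismatch_duplicate_ignored_under_minihuman_tolerance():
    genome = planted_genome(mutate(PROTO, [5, 9]))
    cands = scan_pams(genome)
    target = next(c for c in cands if c.pam_start == 8)
    counts = count_offtargets(target, genome, None, OffTargetPolicy("minihuman"))
    assert sum(counts.values()) == 0


def test_duplicate_without_valid_pam_is_not_a_hit():
    seq = "GCGTGCGT" + "TTTA" + PROTO + SPACER + "TTTT" + PROTO + SPACER + "GCGTGCGT"
    genome = {"chr1": seq}
    cands = scan_pams(genome)
    target = next(c for c in cands if c.pam_start == 8)
    counts = count_offtargets(target, genome, None, OffTargetPolicy("minihuman"))
    assert sum(counts.values()) == 0


def test_benchmark_window_ignores_pam_distal_mismatches():
    """Two mismatches at positions 19-20 sit outside the PAM-adjacent 18 nt:
    a hit under the benchmark policy, not under minihuman (tolerance 1/20)."""
    genome = planted_genome(mutate(PROTO, [18, 19]))
    cands = scan_pams(genome)
    target = next(c for c in cands if c.pam_start == 8)
    bench = count_offtargets(target, genome, None, OffTargetPolicy("benchmark"))
    mini = count_offtargets(target, genome, None, OffTargetPolicy("minihuman"))
    assert sum(bench.values()) == 1
    assert sum(mini.values()) == 0


def test_offtarget_annotation_classes_with_exonic_precedence():
    genome = planted_genome(PROTO)
    ann = pd.DataFrame(
        {"chrom": ["chr1", "chr1"], "start": [40, 40], "end": [80, 80],
         "class": ["intronic", "exonic"], "gene": ["G1", "G1"]}
    )
    cands = scan_pams(genome)
    target = next(c for c in cands if c.pam_start == 8)
    counts = count_offtargets(target, genome, ann, OffTargetPolicy("minihuman"))
    assert counts == {"exonic": 1, "intronic": 0, "intergenic": 0}


def test_offtargets_match_brute_force_on_random_genome():
    rng = np.random.default_rng(33)
    genome = {"c1": "".join(rng.choice(list("ACGT"), size=3000))}
    sites = scan_pams(genome)
    policy = OffTargetPolicy("minihuman")
    for target in sites[:10]:
        expected = {"exonic": 0, "intronic": 0, "intergenic": 0}
        for ch, start, strand, proto in brute_force_scan(genome):
            if (ch, start, strand) == target.site_key:
                continue
            mm = sum(a != b for a, b in zip(target.protospacer, proto))
            if mm <= 1:
                expected["intergenic"] += 1
        assert count_offtargets(target, genome, None, policy, sites=sites) == expected


def test_guide_ranking_is_lexicographic():
    a = cand("A" * 0 + "ACGTACGTACGTACGTACGT", pam_start=0,
             target_transcripts=3, distance_to_first_exon=500)
    b = cand("CCGTACGTACGTACGTACGT", pam_start=30,
             target_transcripts=3, distance_to_first_exon=100)
    c = cand("GCGTACGTACGTACGTACGT", pam_start=60,
             target_transcripts=2, distance_to_first_exon=10)
    d = cand("ACGCGTCTCGTACGTACGTA", pam_start=90, target_transcripts=5)
    for x in (a, b, c):
        x.offtargets = {"exonic": 0, "intronic": 0, "intergenic": 0}
    d.offtargets = {"exonic": 0, "intronic": 0, "intergenic": 0}
    filter_candidates([a, b, c, d])  # d fails bsmbi
    picked = select_guides([a, b, c, d], None, 4, OffTargetPolicy("minihuman"))
    # same transcripts/off-targets/score: closer first exon wins; fewer transcripts last
    assert [p.pam_start for p in picked] == [30, 0, 60]


def test_exonic_offtargets_exclude_under_minihuman():
    a = cand("ACGTACGTACGTACGTACGT")
    a.offtargets = {"exonic": 1, "intronic": 0, "intergenic": 0}
    filter_candidates([a])
    assert select_guides([a], None, 4, OffTargetPolicy("minihuman")) == []
    # benchmark mode tolerates up to two off-targets in total
    assert select_guides([a], None, 4, OffTargetPolicy("benchmark")) == [a]
    a.offtargets = {"exonic": 2, "intronic": 1, "intergenic": 0}
    assert select_guides([a], None, 4, OffTargetPolicy("benchmark")) == []


def test_array_assembly_length_and_limits():
    guides = ["ACGTACGTACGTACGTACGT"] * 4
    dr = "AATTTCTACTCTTGTAGAT"  # 19 nt
    arr = build_array("GENE1", guides, dr)
    assert len(arr.oligo) == 4 * (19 + 20)
    assert arr.oligo == (dr + guides[0]) * 4
    assert arr.construct_id == "GENE1_array"
    single = build_array("GENE2", guides[:1], dr)
    assert len(single.guides) == 1
    with pytest.raises(ValueError, match="empty"):
        build_array("G", [], dr)
    with pytest.raises(ValueError, match="limit"):
        build_array("G", guides * 2, dr)


@pytest.mark.parametrize(
    "n,p,mode,expected",
    [
        (1000, 6, "mono_pairwise", 36_000_000),
        (1000, 6, "multiplexed", 1_000_000),
        (1, 9, "multiplexed", 1),
    ],
)
def test_combinatorial_library_sizes(n, p, mode, expected):
    assert combinatorial_size(n, p, arity=2, mode=mode) == expected


def test_higher_arity_unsupported():
    with pytest.raises(ValueError, match="arity"):
        combinatorial_size(10, 2, arity=3)


def test_array_span_arithmetic():
    a = cand("ACGTACGTACGTACGTACGT", pam_start=100)
    b = cand("ACGTACGTACGTACGTACGT", pam_start=100)
    assert array_span([a, b]) == 0
    c = cand("ACGTACGTACGTACGTACGT", pam_start=3100)
    assert array_span([a, c]) == 3000
    other = cand("ACGTACGTACGTACGTACGT", chrom="chr2", pam_start=100)
    assert array_span([a, other]) is None


def test_designer_end_to_end_selects_the_planted_guides():
    """A single-gene toy genome with exactly two valid planted candidates."""
    p2 = "GACCTGATCGGCTAGCGGTC"
    seq = "GCGTGCGT" + "TTTA" + PROTO + SPACER + "TTTC" + p2 + "GCGTGCGT"
    genome = {"chr1": seq}
    ann = pd.DataFrame(
        {"chrom": ["chr1"], "start": [0], "end": [len(seq)], "class": ["exonic"],
         "gene": ["GENE1"], "transcript_count": [2], "first_exon_start": [0]}
    )
    arrays, manifest = design_library(
        genome, ann, guides_per_gene=4, min_guides=1, direct_repeat="AATT"
    )
    assert len(arrays) == 1
    assert set(arrays[0].guides) == {PROTO, p2}
    assert manifest.loc[0, "status"] == "ok"
    # deterministic: a second run reproduces the same arrays
    arrays2, _ = design_library(
        genome, ann, guides_per_gene=4, min_guides=1, direct_repeat="AATT"
    )
    assert [a.guides for a in arrays2] == [a.guides for a in arrays]
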