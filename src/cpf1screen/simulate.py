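"""Synthetic pooled-screen generator.

Generative model
----------------
Each gene receives ``guides_per_gene`` guides; each guide is independently
functional ("active") with probability ``p_active_guide``.  An active guide
targeting an essential gene carries a per-timepoint-unit log2 dropout effect
drawn from Normal(essential_lfc_mean, essential_lfc_sd); guides targeting
non-essential genes, and inactive guides, have effect 0.

A multiplexed construct's effect is the effect of its *strongest* active
guide (min over per-guide effects, effects being negative) — a conservative
choice that models better sampling of an effective guide from the array
without asserting multi-cut synergy.

Reference abundances per construct are log-normal around ``depth_mean``
(sigma 0.5 in log2 units, emulating cloning skew).  Counts are negative
binomial around ``abundance * 2**(effect * timepoint)``: the dropout rate is
constant in log2 space, so depletion accumulates linearly with time.
Everything is deterministic given ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .types import (
    Construct,
    CountMatrix,
    GuideLibrary,
    NucleaseMode,
    ReferenceSets,
    SampleLabel,
)

#: log2-scale s.d. of reference construct abundances (cloning skew).
ABUNDANCE_LOG2_SD = 0.5

#: Planted positional activity motif: additive shifts to a guide's activity
#: probability per (position, base), position 1 = PAM-adjacent.  The default
#: emulates the strongest known AsCpf1 preference — T at position +1 kills
#: activity, G/C helps — so the scoring pipeline has a recoverable truth.
PLANTED_MOTIF: dict[int, dict[str, float]] = {
    1: {"T": -0.35, "G": 0.20, "C": 0.20, "A": 0.0},
    3: {"T": 0.10, "C": -0.10, "A": 0.0, "G": 0.0},
}


def planted_motif_score(guide: str, motif: dict[int, dict[str, float]] | None = None) -> float:
    """Sum of motif shifts for a guide (position 1 = first protospacer base)."""
    motif = PLANTED_MOTIF if motif is None else motif
    return sum(motif.get(p, {}).get(b, 0.0) for p, b in enumerate(guide, start=1))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic screen.

    Defaults mirror the benchmark screen design: 342 essential and 345
    non-essential genes, 3 guides per gene, triplicates sampled at four
    timepoints, with per-guide activity around one third (the mono-cistronic
    AsCpf1 regime) and a strong per-week essential dropout.
    """

    n_essential: int = 342
    n_nonessential: int = 345
    guides_per_gene: int = 3
    mode: NucleaseMode = NucleaseMode.CPF1_MULTI
    p_active_guide: float = 0.32
    essential_lfc_mean: float = -1.0
    essential_lfc_sd: float = 0.3
    timepoints: tuple[int, ...] = (1, 2, 3, 4)
    replicates: int = 3
    depth_mean: float = 500.0
    nb_dispersion: float = 10.0
    motif_effect: float = 0.0  # 0 = sequence-independent activity; 1 = full planted motif
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", NucleaseMode(self.mode))
        object.__setattr__(self, "timepoints", tuple(self.timepoints))
        if not 0.0 <= self.p_active_guide <= 1.0:
            raise ValueError("p_active_guide must be in [0, 1]")
        if self.essential_lfc_mean > 0:
            raise ValueError("essential_lfc_mean must be <= 0 (dropout)")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.n_essential + self.n_nonessential == 0:
            raise ValueError("at least one gene required")
        if self.guides_per_gene < 1:
            raise ValueError("guides_per_gene must be >= 1")
        if self.replicates < 1 or not self.timepoints:
            raise ValueError("need at least one replicate and one timepoint")


@dataclass
class SimTruth:
    """Planted ground truth: per-guide activity and per-construct effects."""

    guide_active: pd.Series  # bool, indexed by guide_id
    construct_effect: pd.Series  # log2 per timepoint-unit, indexed by construct_id
    essential_genes: frozenset[str] = field(default_factory=frozenset)

    def cumulative_effect(self, timepoint: int) -> pd.Series:
        return self.construct_effect * timepoint


def expected_active_fraction(p_active_guide: float, guides_per_construct: int) -> float:
    """Probability that a construct carries >= 1 functional guide: 1 - (1-p)^k."""
    if not 0.0 <= p_active_guide <= 1.0:
        raise ValueError("p_active_guide must be in [0, 1]")
    if guides_per_construct < 1:
        raise ValueError("guides_per_construct must be >= 1")
    return 1.0 - (1.0 - p_active_guide) ** guides_per_construct


def _random_guide(rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=20))


def _simulate_guides(rng: np.random.Generator, n: int) -> list[str]:
    seqs: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        g = _random_guide(rng)
        if g not in seqs:
            seqs.add(g)
            out.append(g)
    return out


def simulate_screen(
    cfg: SimConfig,
) -> tuple[GuideLibrary, CountMatrix, ReferenceSets, SimTruth]:
    """Draw a complete synthetic screen: library, counts, references, truth."""
    rng = np.random.default_rng(cfg.seed)

    ess_genes = [f"ESS{i:04d}" for i in range(1, cfg.n_essential + 1)]
    non_genes = [f"NON{i:04d}" for i in range(1, cfg.n_nonessential + 1)]
    genes = ess_genes + non_genes
    is_ess = np.array([True] * len(ess_genes) + [False] * len(non_genes))

    k = cfg.guides_per_gene
    seqs = _simulate_guides(rng, len(genes) * k)

    # per-guide activity and per-guide effect (essential genes only)
    p_active = np.full(len(genes) * k, cfg.p_active_guide)
    if cfg.motif_effect != 0.0:
        shift = np.array([planted_motif_score(g) for g in seqs])
        p_active = np.clip(p_active + cfg.motif_effect * shift, 0.0, 1.0)
    active = rng.random(len(genes) * k) < p_active
    raw_eff = rng.normal(cfg.essential_lfc_mean, cfg.essential_lfc_sd, len(genes) * k)
    guide_eff = np.where(
        active & np.repeat(is_ess, k), np.minimum(raw_eff, 0.0), 0.0
    )

    constructs: list[Construct] = []
    guide_ids: list[str] = []
    con_eff: dict[str, float] = {}
    if cfg.mode is NucleaseMode.CPF1_MULTI:
        for gi, gene in enumerate(genes):
            cid = f"{gene}_array"
            gset = tuple(seqs[gi * k : (gi + 1) * k])
            constructs.append(Construct(cid, gene, gset))
            guide_ids.extend(f"{cid}_g{j}" for j in range(1, k + 1))
            # strongest active guide dominates the construct phenotype
            con_eff[cid] = float(guide_eff[gi * k : (gi + 1) * k].min())
    else:
        for gi, gene in enumerate(genes):
            for j in range(k):
                cid = f"{gene}_sg{j + 1}"
                constructs.append(Construct(cid, gene, (seqs[gi * k + j],)))
                guide_ids.append(f"{cid}_g1")
                con_eff[cid] = float(guide_eff[gi * k + j])

    lib = GuideLibrary(constructs, cfg.mode)
    effect = pd.Series(con_eff).reindex(lib.construct_ids)
    truth = SimTruth(
        guide_active=pd.Series(active, index=guide_ids),
        construct_effect=effect,
        essential_genes=frozenset(ess_genes),
    )

    # reference abundance: log-normal (log2 sd) around depth_mean, per construct
    n_con = len(constructs)
    abundance = cfg.depth_mean * np.exp2(rng.normal(0.0, ABUNDANCE_LOG2_SD, n_con))

    samples: list[SampleLabel] = []
    cols: dict[str, np.ndarray] = {}
    disp = cfg.nb_dispersion

    def _nb(mean: np.ndarray) -> np.ndarray:
        mean = np.maximum(mean, 1e-9)
        p = disp / (disp + mean)
        return rng.negative_binomial(disp, p)

    for rep in range(1, cfg.replicates + 1):
        s = SampleLabel(0, rep, is_reference=True)
        samples.append(s)
        cols[s.name] = _nb(abundance)
        for tp in cfg.timepoints:
            s = SampleLabel(tp, rep)
            samples.append(s)
            cols[s.name] = _nb(abundance * np.exp2(effect.to_numpy() * tp))

    counts = pd.DataFrame(cols, index=lib.construct_ids)
    cm = CountMatrix(counts=counts, samples=samples)
    refs = ReferenceSets(frozenset(ess_genes), frozenset(non_genes))
    return lib, cm, refs, truth


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    """Convenience: the same study conditions under a different seed."""
    return replace(cfg, seed=seed)
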