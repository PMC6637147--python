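# cpf1screen

Analysis and design toolkit for **multiplexed AsCpf1 (Cas12a) pooled CRISPR
knockout screens**.

AsCpf1 processes its own crRNA arrays, so a single lentiviral vector can
deliver several guides against one gene — shrinking a genome-wide knockout
library to one construct per gene without giving up targeting efficiency.
That architecture changes the analysis: the construct, not the guide, is the
observational unit, reference sets are small, and library quality is judged
by how many vectors actually cut. `cpf1screen` covers the full desk-side
workflow for such screens:

- **IO / domain model** — guide libraries (mono-cistronic Cas9/Cpf1 or
  multiplexed Cpf1 arrays of 1–7 guides), read-count matrices with one
  reference sample per replicate, gold-standard essential/non-essential gene
  sets (the 342/345 benchmark sets).
- **Simulator** — a negative-binomial generative model of a pooled dropout
  screen (per-guide activity, log-normal cloning skew, linear-in-log2
  depletion), so every downstream stage is testable without any download.
- **Fold change** — depth normalization and log2 fold change against each
  replicate's reference sample.
- **Active-construct calling** — place a depletion threshold at a chosen
  false-positive rate on non-essential-targeting constructs; the fraction of
  essential-targeting constructs beyond it measures library penetrance.
- **Low Fat BAGEL** (`LowFatBagel`, scikit-learn style) — a small-library
  variant of Bayes-factor essentiality classification: across 100
  permutations, ~60% of the *reference guides* train kernel densities of the
  essential and non-essential fold-change distributions; each guide's Bayes
  factor BF = log2 f_ess(x)/f_non(x) is averaged over its held-out rounds
  and summed per gene. Hits are called where reference-set precision reaches
  1 − FDR.
- **PR metrics** — precision-recall curves and average precision over the
  reference sets, the prevalence null baseline (342/687 = 0.498), the
  mAUC/rmAUC separation-rate series
  rmAUC_x = (AUC_x − 0.498)/(AUC_end − 0.498) × 100%, and per-gene guide
  down-sampling.
- **Protospacer scoring** (`ProtospacerScorer`, scikit-learn style) — per
  essential gene, pair the most- and least-depleted guide, bootstrap the
  gene pairs, and average the per-position nucleotide frequency difference
  into a 4×20 score table; a guide's score is the sum of its positional
  cells (> 0 ⇒ predicted high-performing).
- **Library designer** — scan a genome for TTTV PAMs, filter homopolymers
  and BsmBI sites, count 1-mismatch off-targets by annotation class with an
  exhaustive PAM-anchored Hamming scan, rank guides (transcript coverage,
  intergenic off-targets, sequence score, first-exon distance) and assemble
  direct-repeat-separated crRNA arrays; plus combinatorial-library sizing
  (n² multiplexed vs n²p² mono-cistronic pairwise vectors).

## Worked example

```python
import cpf1screen as cs

cfg = cs.SimConfig(n_essential=342, n_nonessential=345, guides_per_gene=3,
                   mode="cpf1_multi", p_active_guide=0.9,
                   essential_lfc_mean=-1.0, timepoints=(1, 2, 3, 4),
                   replicates=3, seed=1)
lib, counts, refs, truth = cs.simulate_screen(cfg)
print(cs.summarize_library(lib))

fc = cs.log2_fold_change(counts)
print(cs.active_fraction(fc, lib, refs, fpr=0.05).summary)

bft = cs.run_lowfat_bagel(fc, lib, refs, cs.BootstrapScheme(100, 0.6, seed=1))
curve = cs.pr_curve(bft.gene_bf, refs)
print(f"gene-level PR-AUC: {curve.auc:.3f}  (null baseline {cs.null_auc(refs):.3f})")
hits, thr = cs.call_hits_at_fdr(bft, refs, fdr=0.01)
print(f"hits at 1% FDR: {len(hits)} genes (BF threshold {thr:.2f})")
```

Output:

```
LibrarySummary(n_constructs=687, n_guides=2061, n_genes=687, n_nontargeting=0,
               guides_per_construct_histogram={3: 687})
   timepoint      mean        sd
0          1  0.612086  0.066506
1          2  0.958090  0.020537
2          3  0.994152  0.000000
3          4  0.998051  0.001688
gene-level PR-AUC: 1.000  (null baseline 0.498)
hits at 1% FDR: 345 genes (BF threshold -6.93)
```

The benchmark-sized multiplexed library (687 arrays, 2061 guides) starts at
61% called-active constructs after one timepoint unit and saturates near the
binomial sampling limit 1 − (1 − 0.9)³ ≈ 0.999 — with 90%-active guides,
almost every 3-guide array carries a functional one. With that penetrance
the Bayes-factor ranking separates planted essentials perfectly (PR-AUC 1.0
against the 0.498 random baseline), and 1%-FDR hit calling recovers
essentially all 342 planted essential genes (plus borderline passengers
admitted by the precision rule).

The same workflow is available from the shell:

```bash
cpf1screen simulate --out-dir sim/ --seed 1
cpf1screen fc --counts sim/counts.tsv --library sim/library.tsv --out fc.tsv
cpf1screen bagel --fc fc.tsv --library sim/library.tsv \
    --essential sim/essential.txt --nonessential sim/nonessential.txt \
    --permutations 100 --seed 1 --out bf.tsv
cpf1screen design --genome genome.fa --annotation exons.tsv --out-dir design/
```

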