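# epidiet

An integrative epigenome analysis toolkit for dietary-obesity studies of the
mouse hypothalamus — and for any design that profiles a tissue with multiple
histone-mark ChIP-seq libraries, MeDIP-seq, RNA-seq and single-nucleus
ATAC-seq across feeding conditions. The package re-implements the full
downstream analysis as a tested, reusable library and ships a synthetic-data
generator that emulates the study's data structure with planted ground truth,
so every stage can be validated end-to-end without any sequencing data.

## What it computes

**Chromatin states.** Genome bins (200 bp) carrying binary occupancy calls
for H3K4me3, H3K27ac, H3K9me3, H3K27me3 and H3K36me3 are segmented with a
hidden Markov chain with independent Bernoulli emissions per mark:

- emission matrix *B* ∈ [0,1]^(K×M), transition matrix *A*, initial law π,
  fitted by Baum–Welch EM with random restarts (K = 6 states by default);
- decoding by posterior marginals (Viterbi behind a flag), plus the state
  statistics used to characterize the segmentation: genome % per state,
  TSS-neighborhood fold enrichment in 200-bp offset bins over ±2 kb, overlap
  fold enrichment against external annotations, and the methylation-by-state
  statistic (fraction of each contiguous state segment covered by MeDIP
  peaks).

**Differential enrichment.** Promoter windows (TSS ± 2 kb; plus gene body for
H3K36me3) are counted by any-overlap and compared between conditions with an
exact conditional count test: counts are rescaled to the geometric-mean
library size and, given their sum *n*, the split follows Binomial(n, ½) with
no overdispersion or the symmetric beta-binomial induced by a common
negative-binomial dispersion φ. Two-sided p-values sum all splits no more
probable than the observed one. Calls use the per-assay cutoffs of the study
design: |log2FC| ≥ 1 for H3K4me3/H3K9me3, ≥ 2 for the other marks and MeDIP,
≥ 0.3 for RNA; α = 0.05 except 0.01 for H3K27ac.

**Integration.** Up-regulation is imputed for genes gaining both activating
marks but neither suppressive mark; down-regulation for the mirrored pattern.
Time-course log2FC triples are classified into the nine trend profiles by the
slope rule (|Δ| ≥ 1 between adjacent durations), RNA×ChIP concordance is
computed as a Sankey-ready edge table, Venn region counts are exact, and
gene-set enrichment is an upper-tail hypergeometric test with BH adjustment.

**snATAC layer.** Fragment ingestion with the +4/−5 transposase shift, the
four-threshold QC filter (≥ 200 fragments in peaks, ≤ 95th-percentile
fragments, nucleosome signal ≤ 4, TSS enrichment ≥ 2), gene-activity scoring
over extended gene bodies, TF-IDF/LSI normalization, cell-type composition
change between conditions, and per-cell-type differential gene activity by
rank-sum testing with BH adjustment.

## Worked example

```python
import numpy as np
from epidiet.simulate import (SimulationConfig, make_toy_genome,
                              simulate_state_path_and_marks, simulate_mark_reads)
from epidiet.chromstate import fit_state_model, decode_states, state_genome_fractions
from epidiet.diffenrich import differential_table, classify_calls
from epidiet.integrate import MarkCallSet, impute_up_genes

cfg = SimulationConfig(seed=11)              # 2 x 200 kb genome, 60 genes
genome, genes = make_toy_genome(cfg)
path, marks = simulate_state_path_and_marks(cfg, genome)
sim = simulate_mark_reads(cfg, genome, genes)  # plants 12 genes at log2FC = 3

model = fit_state_model(marks, n_states=6, seed=0)
states = decode_states(model, marks)
print(np.round(state_genome_fractions(states), 1))

tables = {}
for mark in cfg.marks:
    df = differential_table(sim.counts[("HFD-1M", mark)],
                            sim.counts[("Chow-3M", mark)],
                            sim.library_sizes[("HFD-1M", mark)],
                            sim.library_sizes[("Chow-3M", mark)],
                            dispersion=cfg.dispersion)
    tables[mark] = classify_calls(df, mark)
up = impute_up_genes(MarkCallSet.from_call_tables(tables))
planted = set(sim.planted_genes)
print(f"imputed up: {len(up)}; recovered {len(up & planted)}/{len(planted)} planted")
```

prints

```
[ 6.   1.3  4.2  4.7 77.3  6.4]
imputed up: 12; recovered 12/12 planted
```

The first line is the percentage of the toy genome assigned to each of the
six states after relabeling (S1 most active-promoter-like; the two quiescent
states dominate, as in real chromatin). The second line shows that every gene
planted with a gain of both activating marks was recovered by the
differential tests plus imputation logic, with no false inclusions.

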