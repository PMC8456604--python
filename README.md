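# tcrgamma

Germline annotation, read simulation and repertoire analysis for the chicken
T-cell receptor γ (TCRγ) locus.

The chicken is a "γδ-high" species: γδ T cells can make up half of its
circulating lymphocytes, and the TCRγ chain repertoire is correspondingly
rich.  The locus is a translocon — an array of Vγ gene segments upstream of
three Jγ segments and a single Cγ gene — and expressed diversity arises from
somatic Vγ–Jγ recombination with junctional trimming, palindromic (P) and
non-templated (N) nucleotide additions.  This package provides, for that
system:

* **germline** — a model of germline V/J/C segments (IMGT-style FR/CDR
  region annotations, recombination signal sequences, functionality classes),
  with conserved-anchor validation (1st-CYS, TRP, 2nd-CYS), RSS scanning
  against the CACAGTG / ACAAAAACC consensus, and single-linkage subgroup
  clustering at the ≥ 70 % nucleotide-identity criterion;
* **reference** — a synthetic germline database transcribing the published
  inventory's structure: 44 Vγ in six subgroups (6/19/9/4/3/3 members,
  28 potentially functional), 3 Jγ, 1 Cγ;
* **simulate** — a 5′ RACE amplicon simulator: weighted V–J recombination
  with truncated-geometric trims, P/N insertions, a 12-nt sample barcode at
  the Cγ-primer end, paired 250-bp reads, and a per-read ground-truth table;
* **pipeline** — the read-processing chain: overlap merge → barcode
  demultiplex → unique V-region dereplication → seeded V/J assignment →
  pseudogene/ORF filter → CDR3γ extraction → clonotype collapse.  CDR3γ is
  the sequence strictly between the `TAC(T/C)A(T/C)TG(T/C)` (Tyr(Tyr/His)Cys)
  and `TT(C/T)GG(C/A)(A/T)(C/G)(A/T)GG(A/T)` (Phe-Gly-X-Gly) motifs, and a
  CDR3 is *productive* iff its length ≡ 0 (mod 3) and its translation is
  stop-free;
* **repstats** — segment/subgroup usage, the V×J pairing matrix, CDR3 length
  summaries, amino-acid composition split into normal (4–22 AA) and
  ultralong (23–36 AA) bands, and filter-retention arithmetic;
* **dotplot** — a dotmatcher-style windowed-identity self-plot (300-bp
  window, 70 % identity) with detection of off-diagonal homology runs, the
  signature of tandem duplication in the V region of the locus.

## Worked example

Simulate a four-sample run, process it, and summarise:

```python
from tcrgamma import *
from tcrgamma.pipeline import PipelineConfig
from tcrgamma.simulate import SimulationConfig

db = build_reference_db()
cfg = SimulationConfig(n_sequences=1000, seed=1)
ds = simulate_dataset(cfg, db)
pcfg = PipelineConfig(barcodes=cfg.barcodes, primer_len=cfg.amplicon_c_prefix_len)
clono, report, totals = run_pipeline(pcfg, db, ds.r1, ds.r2)
print(report.to_string(index=False))
print(segment_usage(clono, "J").round(4).to_string())
```

prints

```
sample_id  demultiplexed  unique_vregion  vj_assigned  functional_v  cdr3_extracted  clonotypes  productive
       S1            261             258          258           258             258         258          74
       S2            242             240          240           240             240         240          78
       S3            236             234          234           234             234         234          72
       S4            261             260          260           260             260         260          81
j_call
Jg1    0.3679
Jg2    0.2278
Jg3    0.4042
```

All 1000 pairs merge and demultiplex; dereplication collapses a handful of
identical rearrangements (261 → 258 unique V-region sequences in S1); every
unique sequence is assigned a functional V (the simulator only rearranges
functional segments) and yields a CDR3; roughly 30 % of clonotypes are
productive, as expected when junctions land in a random reading frame and
must also avoid stop codons.  The recovered Jγ usage (0.368 / 0.228 / 0.404)
matches the configured weights (0.3558 / 0.2204 / 0.4238) to within sampling
noise.

A command-line interface mirrors the library:

```sh
tcrg simulate --n 1000 --seed 1 --out scratch/run
tcrg run --r1 scratch/run_R1.fastq --r2 scratch/run_R2.fastq --out scratch/run
tcrg stats --clonotypes scratch/run_clonotypes.tsv --out scratch/run
tcrg dotplot locus.fasta --window 300 --threshold 0.70 --min-run 1000 --out scratch/locus
```

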