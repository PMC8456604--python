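# Methods

## The system being modelled

The chicken TCRγ locus is a translocon: ~44 germline Vγ segments upstream of
three Jγ segments and one Cγ gene.  Expressed γ chains arise by somatic
Vγ–Jγ recombination; the hypervariable CDR3γ spans the junction, delimited
by the second conserved cysteine of the V domain and the phenylalanine of
the J-encoded Phe-Gly-X-Gly motif (the anchor codons themselves are
excluded).  Junctional diversity comes from exonucleolytic trimming of the
V 3′ and J 5′ ends, palindromic (P) nucleotides at untrimmed ends, and
non-templated (N) insertions.

This package implements the germline model, a read simulator for 5′ RACE
amplicon libraries of that locus, the read-processing pipeline that turns
paired reads into clonotypes, repertoire statistics, and a dot-plot
analyzer for the tandem-duplication structure of the locus itself.

## Germline model

A segment carries its coding sequence (`seq_nt`), an optional leader, a map
of FR1/CDR1/FR2/CDR2/FR3 half-open intervals on `seq_nt` (V only), an
optional RSS annotation and a locus placement.  All internal coordinates
are 0-based half-open.

**Anchors.** The numbering map used here fixes the 1st-CYS ("C23") at the
last codon of FR1, the conserved TRP ("W41") as any in-frame Trp codon in
FR2, and the 2nd-CYS ("C104") at the last codon of FR3.  A leader or region
boundary that is not a whole number of codons flags a frameshift.

**Functionality.** A V segment is *pseudo* iff its reading frame is broken
(internal stop or frameshift across leader+V); *ORF* iff the frame is
intact but an anchor is absent or (by default) no intact RSS is annotated;
*functional* otherwise.  This is total and deterministic, so the three
classes partition any input set.  "Intact RSS" means at most 2 heptamer and
3 nonamer mismatches against CACAGTG / ACAAAAACC; these tolerances, and
whether an RSS is required at all, are arguments — no published threshold
exists for what counts as an RSS defect.  The V-side spacer defaults to
23 nt (the standard single-turn/double-turn pairing with the 12-nt J-side
spacer); both values are explicit fields.

**RSS scanning** slides the heptamer + spacer + nonamer template over the
provided strand and reports per-motif mismatch counts.  The scanner always
reads heptamer-first: for a 5′ RSS, pass the RSS-bearing strand (the
reverse complement of the genomic top strand).  It is checked exactly
against an exhaustive all-offsets scan.

**Subgroup clustering** is single-linkage over pairwise global alignment
identity (matches / alignment columns, end gaps penalized, computed from an
edit-distance-optimal alignment path), thresholded inclusively at 0.70, over
the FR1-start..FR3-end span — the same span conventionally used for V-gene
phylogenetics; whether the published criterion used the full V-REGION or
FR1–FR3 is not stated, and we fix the latter.  Cluster labels are assigned
in 3′→5′ order of each cluster's 3′-most member (largest start coordinate on
a forward-strand translocon), making labels invariant under input
permutation.

## The reference database

The published germline nucleotide sequences are not redistributable, so the
bundled database is **synthetic**: it transcribes the inventory's structure
(ids, subgroup membership, functionality classes, the 6/19/9/4/3/3 subgroup
sizes with 3/14/8/3/0/0 functional members, germline CDR3 contributions of
15/15/23/13 bp for subgroups 1–4 when joined to a 6-nt J head) onto
deterministic, seeded random sequences.  Each subgroup grows from an
ancestor with planted anchors; members carry ~3.5 % substitutions (~8.5 %
for the diverse Vγ2 subgroup), pseudogenes carry two in-frame stops, and
ORF members lack one anchor or the RSS.  Two builder invariants matter
downstream: germline CDR3 tails are T-free, and all spurious occurrences of
the two CDR3 anchor motifs are scrubbed, so an anchor motif can only occur
where biology puts it.  Between-subgroup identity lands near the ~55 %
expected for unrelated sequences, comfortably below the 0.70 criterion.

## Simulator

`SimulationConfig` holds the study conditions; defaults are chosen once:

| parameter | default | rationale |
|---|---|---|
| V weights | reported usage for Vγ3.7/Vγ2.13/Vγ1.6/Vγ1.3 (20.58/19.84/16.00/10.15 %) and Vγ4.1/Vγ4.3 (0.19/0.03 %); remainder uniform over the other 22 functional V | the dominant-segment structure of the thymus repertoire |
| J weights | 35.58 / 22.04 / 42.38 % for Jγ1/2/3 | reported usage |
| trim length | min(Geom(0.35), cap 10), per end; additionally capped at the germline CDR3 tail so trimming never removes an anchor codon | "very common" but short trims; keeps every junction extractable |
| P nucleotides | 0–2 nt, only when the corresponding end is untrimmed | standard recombination biology |
| N insertion | min(Geom(0.15), cap 15), uniform bases | reproduces a broad, roughly Gaussian CDR3 length spread |
| read length | 250 bp paired; amplicon must lie in [250, 500) so mates overlap | Illumina 2×250 layout of the source libraries |
| barcodes | four 12-nt tags, pairwise Hamming distance 12 | one tag per sample at the 5′ end of the Cγ primer |
| errors | substitutions only, constant Q37, no indels | the pipeline's merge/assignment logic is substitution-focused |

The amplicon is UTR + leader + trimmed V + P/N/P + trimmed J + a 30-nt Cγ
prefix + reverse-complemented barcode, in mRNA orientation.  The truth
record stores segments, trims, inserts, the constructed CDR3 and its
productivity; reassembling the transcript from the truth record reproduces
the emitted amplicon exactly (tested).  Identical seeds give byte-identical
output.

What the simulator does **not** model: PCR bias, chimeras, indel errors,
UMI structure, non-functional-V rearrangements (weights cover functional
segments only), and real junction-length distributions — the published data
do not quantify them, so defaults reproduce the qualitative spread only.
Passing round-trip tests therefore demonstrate correctness of the
processing chain under these idealized conditions, not performance on real
thymus libraries.

## Pipeline

Stage order: merge → demultiplex → dereplicate unique V-regions →
V/J assignment → pseudo/ORF filter → CDR3 extraction → clonotype collapse →
productivity.  Dereplication before assignment reproduces the published
count bookkeeping (unique V-region sequences first, then the 369/222/235/324
pseudo/ORF drops, then the productivity filter); CDR3 extraction must
precede clonotype collapse because the clonotype key is (sample, V, J,
CDR3-nt).  Every stage's drops are counted; per-sample counts are monotone
non-increasing along the chain.

**Merging** slides the reverse-complemented mate against the forward read
and takes the longest overlap with mismatch fraction ≤ 0.25 (minimum
10 bp); overlap mismatches resolve to the higher-quality base.

**Demultiplexing** reads the barcode from the amplicon 3′ end
(reverse-complemented), re-orienting C→V input first; one mismatch is
tolerated by default, and barcode sets whose pairwise distance does not
exceed twice the tolerance are rejected outright.  The barcode and the
Cγ primer site are stripped so the retained insert is exactly the V-region
sequence (read start through J end) used for dereplication.

**V/J assignment** shortlists candidate V segments by exact shared 12-mers,
aligns each candidate semi-globally into the read, and scores the
resulting alignment path with +1 match, −2 mismatch, −4 gap open, −1 per
gap base; trailing germline-only bases (the trimmed V 3′ end) are excluded
from the scored span.  J is sought downstream of the V span with leading
germline-only bases (trimmed J 5′ end) excluded.  Ties break by identity,
then id.  Floors: V identity ≥ 0.80 over ≥ 50 bp; J span ≥ 20 bp.  The
alignment engine is edlib; at the ≤ 2 % divergence this pipeline operates
on, the edit-optimal path is the score-optimal one in practice.  Scoring
constants and floors are operational defaults exposed in `PipelineConfig`.

**CDR3 extraction** takes the *last* V-anchor motif within 54 bp upstream
of the V alignment end (extending ≤ 9 nt past it — the anchor sits at the
FR3 terminus, and the window bound suppresses spurious upstream matches)
and the *first* J-anchor motif after it.  The V-side motif is the literal
`TAC(T/C)A(T/C)TG(T/C)` nonamer.  Extraction agrees with a brute-force
dual-motif scan of the whole read whenever both succeed (tested).

## Statistics

Frequencies are computed over unique clonotypes by default, matching an
analysis of unique sequences; `weighting="abundance"` weights by read
count.  Parameter-recovery tests use abundance weighting deliberately:
unique-clonotype weighting collapses duplicate junctions and is not an
estimator of the configured draw distribution.  CDR3 summaries use sample
SD (n−1) by default (configurable) and cover productive clonotypes only,
so every length is a multiple of 3 and the AA mean is exactly the nt
mean / 3.  Amino-acid composition pools residues within the normal
(4–22 AA) and ultralong (23–36 AA) bands; the four-class table
(hydrophobic A,V,L,I,P,F,M,W,G,C; neutral-hydrophilic S,T,N,Q,Y; acidic
D,E; basic K,R,H) is a documented convention — the exact published
four-class membership is not enumerated — and is fully configurable.
Retention arithmetic: post-filter = unique − pseudo/ORF-dropped,
productive % = 100 × productive / post-filter.

## Dot-plot

Ungapped dotmatcher-style windows (default 300 bp, 70 % identity, forward
strand), midpoint-anchored on a stride grid; clipped boundary windows are
skipped, not padded.  Self-plots compute the j ≥ i half and mirror it.  Run
detection merges same-diagonal dots separated by ≤ 2 × stride (small-indel
tolerance; gapped chaining is out of scope), reports the j > i half of
self-plots excluding the main diagonal, and filters runs below 1 kb.  Run
length is window-inclusive extent on the first sequence.  The
implementation is verified against a naive per-window recomputation; on a
synthetic locus of four ~17-kb tandem units (independent 5 % divergence per
copy, ≈ 90 % pairwise identity) it recovers the three off-diagonal runs at
unit-length offsets, mirroring the duplication structure of the natural
locus.  Stride 1 is exact; stride 10 is used for inputs beyond ~50 kb.

## Problem sizes and numerical conventions

Round-trip validations use 5,000 read pairs (error-free and at 0.5 %
substitution) and parameter recovery uses 10,000 — sizes at which binomial
noise on a frequency is ~0.005, well inside the ±0.02 recovery band the
package tests.  Thresholds are inclusive (identity ≥ 0.70; dot identity
≥ threshold).  Assignment ties break deterministically (score, identity,
id); clonotype representatives break count ties lexicographically.
Degenerate inputs: empty databases load but are flagged unusable; empty
clonotype tables raise in the statistics layer; an empty CDR3 is in-frame
and translates to the empty peptide.

## Known limitations

The synthetic germline shares only structure, not sequence, with the real
locus, so absolute CDR3 lengths (germline tails 7–17 nt) are shorter than
the real repertoire's 38.69 ± 7.06 nt mean; length statistics here
demonstrate machinery, not biology.  The assigner assumes the read contains
most of the V segment (5′ RACE full-length cDNA); heavily fragmented input
would need local seeding along the read.  Reverse-strand dot-plots and
gapped chaining are not implemented.
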