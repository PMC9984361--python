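# Methods

## Model of the library artifact

A *trans*-spliced mRNA is `SL + body + polyA`; transcript references contain
only `body`, so the SL is soft-clipped. During direct-cDNA library
preparation, the first-strand cDNA of such an mRNA ends in the reverse
complement of the SL's 5' `GG`; those two bases can pair with cytosines of
the `CCC` motif ~12 nt into the SL copy, self-priming second-strand
synthesis on the same molecule. The resulting covalent hairpin sequences as
a single read. In reference orientation it is

```
[second-strand copy][partial antisense SL / stem][SL][body][polyA]
          (second strand)                        (first strand)
```

with everything left of `body` soft-clipped. Only the first strand
base-calls well, so the read maps antisense and the soft-clip quality drops.
Non-*trans*-spliced mRNAs whose 5' terminus is self-complementary
(`body[0:2]` pairing ~12 nt in) produce the same artifact without an SL —
the *endogenous hairpin* class.

The simulator implements exactly this construction. The fold-back point
(`fold_offset`, default 12) is where the copied template starts; the copy
length is drawn uniform per read (`copy_len_range`, default 150–500 nt),
which is what spreads the soft-clip length distribution. The stem pairing
itself is 2 bp (`GG`/`CC`), the minimal geometry consistent with the
SL structure.

## Simulator parameters (defaults = the modeled study conditions)

| parameter | default | meaning |
|---|---|---|
| `n_genes` / `reads_per_gene` | 30 / 50 | genes and mean reads per gene |
| `operon_fraction` | 0.15 | genes placed ~`sl2_distance_mode` nt downstream of a neighbor |
| `sl2_distance_mode` ± `spacing_jitter` | 100 ± 15 nt | operonic intergenic spacing |
| `endogenous_hairpin_fraction` | 0.15 | genes with a 5' stem instead of an SL |
| `hairpin_artifact_prob` | 0.95 | P(molecule becomes a hairpin cDNA) → antisense fraction |
| `err_first_strand` / `err_second_strand` | 0.05 / 0.15 | total per-base error per strand, split sub/ins/del = 0.6/0.2/0.2 |
| `q_aligned` / `q_softclip` | Q14 / Q7 | mean emitted PHRED per strand (Normal, sd 3, clamped [2, 41]) |
| `operon_sl2_prob` / `isolated_sl2_prob` | 0.9 / 0.02 | P(SL2 family) by gene context |
| SL repertoire | SL1 + 11 SL2 variants | synthetic 22-mers with 5' `GG` and `CCC` at 10–12 |

The SL sequences are *synthetic*: they carry the structural properties that
drive the artifact (length 22, 5' `GG`, central `CCC`) but are
rejection-sampled random sequences (pairwise Hamming distance ≥ 8, also
against reverse complements), not any organism's real repertoire. Within-SL2
sampling weights default to a skewed family (SL2.1 21%, SL2.8 15%, rest
uniform), the qualitative shape of observed SL2 usage. Transcript bodies are
rejection-sampled so that (a) no SL or its reverse complement occurs
verbatim and (b) the error-free upstream window of a hairpin read of that
transcript triggers no SL detection under default settings. Without (b),
weak spurious detections in effectively random windows would contaminate the
hairpin class; with it, zero-noise classification is exact.

What the simulator does **not** model: pore signal/kinetics (quality is an
i.i.d. Normal per strand, real quality decays gradually), supplementary
alignments of the second-strand copy, chimeras/PCR artifacts, alternative
*trans*-splice acceptor positions (all reads start at transcript position
0), and reference/annotation errors. Passing tests therefore demonstrate
correctness of the analysis logic under the artifact model, not robustness
to every property of real libraries.

## Detection thresholds and numerical choices

* **Scoring** (+1/−1, gaps −2 affine with equal open/extend) makes scores
  read as "matches − 2·(mismatch budget)": the confidence bound (score > 9)
  and the high-score remark (> 15) map onto mismatch budgets of a 22-nt SL.
* **Per-length detection threshold** `T(L) = max(L − 4, 10)`. `L − 4`
  tolerates two substitutions at any truncation. The floor of 10 re-uses the
  confidence bound: an unfloored two-mismatch budget on an 8-mer (threshold
  4) would fire somewhere in essentially every 100-nt window across a
  repertoire of a dozen SLs and 8 truncation steps, destroying the
  SL-negative precondition of the hairpin test. With the floor, the measured
  false-positive rate on SL-free random windows is below 1% per read.
* **Trimming loop**: trim 2 nt per retry while the truncated SL is ≥ 7 nt
  (22-nt SLs are effectively tested down to 8). The loop stops at the first
  passing truncation; an `exhaust_truncations` flag keeps the best passing
  truncation instead (the two differ only when a shorter truncation would
  outscore the first hit, which does not occur with the default `T`).
* **Ambiguity**: best-score ties are resolved first toward the larger
  matched length, then declared `SL.X` (across families) or `SL2.X` (among
  SL2 variants). A tie among multiple SL1 variants — impossible with the
  default single-SL1 repertoire — is emitted as `SL1.X` by the same logic.
* **Hairpin rule**: probe = last 13 clip bases + first 2 aligned bases
  (−13..+2, 15 nt); reverse-complemented and locally aligned (same scheme)
  against the read's own first 30 aligned bases; called when ≥ 12 columns
  are identities. Matching read-side (not reference-side) makes sequencing
  errors hit both sides of the comparison consistently. `matched_nt` is the
  maximum identity count among maximum-score local alignments (ties then to
  the leftmost start), which makes the 12-of-15 boundary deterministic.
* **Tie-breaks elsewhere**: semi-global alignment returns the smallest
  target end among equal scores; the dominant start of a gene is the most
  supported position, ties toward the 5'-most coordinate.
* **Degenerate inputs**: empty windows are valid (no detection); clips
  < 13 nt cannot be probed and stay `unidentified`; aligned regions shorter
  than the probe bound `matched_nt` from above; empty read sets give
  NaN fractions rather than errors.

## Classification and summaries

SL detection runs on every primary alignment's upstream window (sense reads
included — a sense read with a clipped SL is still *trans*-spliced
evidence); the stem test runs only on antisense SL-negative reads, since
only first-strand reads carry the fold-back signature. SL-negative sense
reads are `sense_untested`. With `sl1_primed` set (libraries where an SL1
oligo primes second-strand synthesis), sense reads are excluded from SL
counting entirely.

Gene-level calls are made at the dominant start. The SL fraction denominator
is SL + hairpin + unidentified reads by default; `unidentified` reads (long
antisense clips whose stem could not be retrieved) are kept because they are
hairpin-like but unresolved, and a flag excludes them. SL2/SL1 ratios use
only confident, family-unambiguous matches: `SL.X` is excluded, `SL2.X`
counts toward SL2 family totals but not variant profiles. Upstream distances
are strand-aware gene-start-to-neighbor-3'-end gaps against protein-coding
genes (all genes when no biotype is annotated), 0 for overlaps, undefined
for the first gene of a contig.

## Problem sizes

Tests and the acceptance script run the simulator at 2,000–10,000 reads over
10–40 genes, sizes at which binomial 3-SD checks on the recovered antisense
fraction, SL2 variant weights and gene-status proportions are already tight
(a few percent). The positional quality profile supports seeded
subsampling (`sample_n`) for larger inputs.

## Known limitations

* Under combined 5%/15% strand noise, the strict 12-of-15 *identity* rule
  caps endogenous-hairpin read recovery near ~82–84%: with a per-column
  corruption probability of ~0.19 on the 15-nt probe, the binomial
  probability of ≤ 3 corrupted columns is ~0.7, and gapped alignment rescue
  recovers only part of the remainder. Gene-level hairpin calls are far more
  robust (majorities at covered genes survive per-read dropout).
* The detector consumes transcriptome (unspliced) alignments only; spliced
  genome alignments are out of scope.
* Start positions are aggregated at exact transcript coordinates by default
  (`collapse_window=0`); real aligners jitter starts by a few nt, for which
  a ±2 nt collapse window is available.
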