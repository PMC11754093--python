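# Methods

## Scope and model

The package analyses a structure-first cytidine deaminase screen in two
stages. The *discovery* stage treats each candidate protein as a point in
a pairwise similarity space given by the template-modelling (TM) score of
its predicted 3D structure against every other candidate, and partitions
the candidates by a greedy leader rule. The *screening* stage treats each
sgRNA-target construct as an amplicon deep-sequencing experiment and
estimates, per protospacer position with a reference C, the fraction of
reads carrying a C-to-T conversion, from which window, context, purity,
nonsense and specificity statistics derive. Computing TM-scores from
coordinates, structure prediction, and homology search itself are outside
the package: their outputs (TM pair tables, per-sequence hit tables,
protein FASTA) are the inputs.

## Discovery stage

**Candidate filtering.** A candidate is kept when its sequence starts with
methionine, it is judged full-length, and its full-sequence E-value beats
the cutoff strictly (`< 0.01`, default). Two domain modes exist:
`require_any` (default; at least one of the two APOBEC-like domain
profiles below the cutoff) and `require_both`. Protein FASTA conventionally
omits the terminal stop, so completeness is policy-driven: in `auto` mode
the terminal-`*` flag is required only when at least one record in the
batch carries one, otherwise the check is skipped with a warning. Each
rejected record carries exactly one primary reason, in the priority order
`no_start_met` → `no_terminal_stop` → `no_hit` → `evalue_above_cutoff`.
The tblout parser reads the full-sequence E-value (column five); the
best-domain E-value is a plausible alternative reading of the filter and is
deliberately not conflated with it.

**TM normalization.** The TM-score is normalized by a protein length, and
the choice matters: normalizing by the longer partner gives the lower
score. The matrix stores both normalizations per pair and resolves a
directed lookup `(center, other)` by mode. The default `by_first` uses the
score normalized by the center's length; because leader centers are always
the longest remaining proteins, this coincides with the conservative
by-longer convention. `by_longer`, `by_shorter` and `symmetric_min` are
retained for sensitivity analysis, because the normalization actually
attached to a published threshold is rarely stated. Missing pairs resolve
to 0.0 — absent evidence never merges proteins.

**Leader clustering.** Proteins are visited in descending length order
(ties broken by lexicographically smallest id, a deterministic choice the
procedure itself does not dictate); the longest unclustered protein seeds a
cluster and absorbs every unclustered protein scoring strictly above the
threshold (default 0.7) against it; members never participate again.
Clusters are numbered in creation order. The procedure is verified
bit-identical against a naive per-iteration re-derivation on hundreds of
random instances, and exact (ARI = 1.0) on planted partitions whose
within/between score supports are separated around the threshold.

**UPGMA.** The hierarchical alternative runs size-weighted average-linkage
agglomeration (scipy's `average` linkage, which is UPGMA) on a
dissimilarity matrix, by default `1 − min(TM_a, TM_b)` — the symmetric-min
transform is our choice, made explicit because no standard exists. Node
heights are half the merge distance, so the tree is ultrametric and
leaf-to-leaf path length reproduces the cophenetic distance; ultrametric
inputs are recovered exactly (1e−9). Trees serialize to Newick.

**Representative sampling.** Per cluster of size `n`,
`k = max(1, ⌈fraction · n⌉)` members (default fraction 0.10) are drawn
uniformly without replacement. The original screen drew with a
system-time-seeded generator, which is irreproducible by design; the
package instead requires an explicit seed, and sorts members before
sampling so the draw depends only on the seed and the cluster content, not
on input ordering.

## Screening stage

**Alignment.** Reads are globally aligned (Needleman–Wunsch; match +2,
mismatch −1, linear gap −2; N mismatches everything) against the amplicon
in both orientations, keeping the higher score; reads below 60% of the
perfect score are discarded as low quality. The aligner is Biopython's
`PairwiseAligner` (exact, C implementation). When the read has amplicon
length and the gapless comparison already attains the optimal score —
the overwhelmingly common case — the pure-substitution alignment is used
directly, which also realizes the substitution-over-gap preference;
otherwise the aligner's deterministic first traceback is taken. Scores are
verified against brute-force enumeration on short pairs.

**Classification and counting.** A read is `indel` when any insertion or
deletion overlaps the quantification window (default protospacer positions
1–20), else `substituted` when it mismatches inside the window, else
`reference`. Indel reads are excluded from all substitution denominators
(the CRISPResso-style convention); per-position base counts therefore sum
exactly to the non-indel read count, an invariant the tests enforce.
`f_p` is the T count over non-indel coverage at each reference-C
protospacer position; on a − strand protospacer the amplicon-strand
observation of a C-to-T edit is G-to-A, and the mapping is handled
internally so every report speaks protospacer-strand coordinates C1–C20
with the PAM at 21–23. Zero-coverage positions are flagged undefined, never
reported as 0.

**Editing window.** With `m = max f_p`, the qualifying set is
`{p : f_p ≥ 0.5·m}` (the ≥50%-of-maximum rule; threshold configurable) and
the reported span runs from the first to the last qualifying position even
across interior dips, matching how windows like "C2–C7" are conventionally
quoted; the raw qualifying set is also emitted. A maximum below `min_peak`
(default 0.01) yields an empty window rather than a meaningless span.
Raising the relative threshold can only shrink the qualifying set
(monotonicity, property-tested).

**Context, purity, indels, aggregation.** Context preference averages
`f_p` by the 5′ neighbour of each edited C on the protospacer strand
(position 1 uses the base upstream of the protospacer), default positions
3–7. The edit-type matrix counts ref→alt substitution events inside the
window on the protospacer strand, normalized by total substitution events
(per-ref-base normalization available). Library aggregation reports mean,
median and quartiles (linear interpolation, declared in the output) of the
per-target efficiency scalar. Two scalar definitions are implemented
because screens quote both: `max_position` (default; the peak per-position
frequency) and `mean_window`; neither is asserted as canonical.

**Consequence calling.** A small gene model (CDS segments with frame,
donor GT / acceptor AG sites, optional ATG start) maps amplicon positions
to codons on the coding strand. A substitution-only allele is
`stop_gained` when a non-stop reference codon now reads TAA/TAG/TGA,
`splice_disrupted` when any base of a canonical donor/acceptor
dinucleotide changes (a deliberately strict definition),
`start_lost` when the ATG is gone; otherwise `other_coding`, `silent` or
`none`. Edits inside an existing stop are `none`. The caller is
chemistry-agnostic — simulators, not the caller, know what a CBE can do.
Nonsense efficiency is the fraction of accepted substitution-only reads
whose call includes a nonsense label; indel reads are excluded by default
(C-to-T purity is the phenotype of interest) with a documented toggle
upstream. Calls are verified against a whole-CDS re-translation oracle
over every single C→T and G→A edit of randomized gene models on both
strands.

**Specificity.** Each R-loop site is quantified with the same per-site
scalar convention as on-target sites; the panel mean excludes (and flags)
undefined sites, and the on:off ratio is `mean_on / mean_off`, undefined —
never pseudocounted — when the off mean is zero.

## Synthetic data: what it emulates, what it does not

The generators are deterministic under an explicit seed and every planted
quantity is serialized in a truth record.

* **Structure sets** draw the by-longer-normalized TM-score of
  within-cluster pairs uniform on [0.72, 0.95] and between-cluster pairs on
  [0.10, 0.60] (both straddle-free around the 0.7 threshold in the
  separated regime, which the config enforces); the by-shorter score adds
  up to 0.03 of non-negative jitter, preserving the fact that
  longer-normalization can only lower a TM-score. Cluster centers are
  forced longest in their cluster. A study-scale size distribution (184
  clusters over 1,483 candidates, 272 representatives under the sampling
  rule) is provided as a synthetic stand-in for a realistic leader-clustered
  screen: a few large clusters and a long tail of small ones.
* **Libraries** are self-targeting constructs: random flanks around a
  20-nt spacer plus NGG PAM, rejection-sampled so every spacer holds ≥1 C
  at protospacer positions 2–8, with a Bernoulli(0.84) draw deciding
  whether each spacer's GC fraction lies inside [0.40, 0.65] — the design
  fractions of a realistic screen library.
* **Reads** are full-amplicon and single-end with a constant Q40 quality
  string; per read, either one 1–3 bp indel inside the protospacer
  (probability `indel_rate`) or independent per-C conversions at
  `base_rate × window_shape(p) × context_multiplier`, plus flat minor
  C→G/C→A channels and uniform per-base sequencing error. Window presets
  cover a narrow C4–C6 editor, an rAPOBEC1-like C4–C7 profile and a wide
  C1–C9 profile.

Deliberate simplifications: no paired-end structure, read-length or
quality model, no PCR duplicates or chimeras, and indel and substitution
events are mutually exclusive per read. Passing tests therefore certify
the quantification logic — alignment, strand handling, denominators,
window/context/purity arithmetic — under known truth; they do not certify
robustness to sequencing physics the simulator does not model.

## Numerical and design choices

* Coordinates are 0-based half-open internally; all reports are 1-based
  protospacer positions.
* Alignment tie-breaks: gapless alignment preferred when optimal;
  otherwise the aligner's deterministic first traceback. Window peak ties
  resolve to the smallest position; center-length ties to the smallest id.
* Quantile convention: linear interpolation, stated in output metadata.
* No quality trimming by default; the screen's chemistry produces
  essentially uniform high-quality amplicon reads and the alignment score
  threshold already discards junk.
* Barcode demultiplexing assigns only unique within-budget best matches;
  ties and over-budget reads are never best-effort assigned.
* Degenerate inputs: empty structure set clusters to an empty partition
  (not an error); a target with zero accepted reads is reported and the
  screen continues; all-undefined profiles raise.
* Exit codes: 0 success, 2 config error, 3 data error, 4 empty result.

## Problem sizes

The shipped analyses and checks use a 1,483-protein / 184-cluster
structure set (≈1.1 M pair scores), a 102-target library at 2,000× depth,
four R-loop sites at 2,000×, 200 random clustering instances (5–60
proteins), 500 short alignment pairs, 100 random gene models and 30 random
8-leaf trees — sizes at which every binomial bound used in the tests is
sharp and a full end-to-end run completes in minutes on one CPU.

## Known limitations

* The leader clustering is exactly the greedy rule: no refinement pass, no
  sensitivity to near-threshold scores beyond the strict inequality.
* Multi-segment CDS models assume segments are listed in coding order with
  consistent frames; codons split across an amplicon edge are skipped, not
  imputed.
* The efficiency scalar for a target is a summary choice, not an estimate
  of a single biological parameter; both provided definitions are biased
  differently at low depth (the max-statistic upward, the window mean by
  dilution).
* The on:off ratio propagates no uncertainty; at very low off-target means
  it is numerically unstable, which is why a zero off mean is flagged
  undefined instead of returned as infinity.
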