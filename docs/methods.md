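# Methods

## The measurement model

A saturation library of all 8,000 CXXX motifs is expressed on a reporter
whose prenylation is required for growth at the selective temperature
(37 °C) but not at the permissive temperature (25 °C). After competitive
growth, amplicon sequencing counts each motif in every replicate culture.
The package's estimand is the per-motif enrichment factor

EF(m) = (v₃₇(m) + c) / (v₂₅(m) + c),

where v is the motif's pooled abundance per condition and c = 1 a
pseudocount. Counts are pooled across replicates *before* frequencies are
formed (sum, then normalize), matching the screen's design in which
replicates are technical splits of one thawed library aliquot.

**Pseudocount scale.** A +1 offset is only meaningful on a count-like
scale: applied to fractional frequencies (~10⁻⁴) it would pin every EF to
≈ 1. The default scale is counts per million of the pooled condition
(`cpm`), with `raw_count` and literal `fraction` modes selectable; the
mode is written into the EF table metadata and propagated to all
downstream outputs. Motifs absent from both conditions keep EF = 1 rather
than being dropped, so every 20-member contextual group stays complete.

## Read extraction

Reads are assigned by exact search for a fixed 21-nt anchor whose last
three bases are the cysteine codon; the nine bases that follow are the
variable codons, translated by the standard genetic code. Extraction is
position-independent (anchor search, not offset), falls back to the
reverse complement, and gates each read on the mean Phred score of the
9-nt insert (default ≥ 20). Stop codons and non-ACGT bases reject the
read — the trimer-phosphoramidite library design contains no stops, so
they indicate artifacts. Every read is either assigned or tallied under a
rejection reason; `assigned + rejected = total` is asserted per file.
Replicate-level QC drops replicates whose fraction of reads with mean
Phred ≥ 30 falls below 0.8; the screen this models reported a global
~96% Q30 rate and the loss of one selective-condition replicate, but not
the exact rule, so the gate (and its threshold) is our choice and is
recorded in the QC report.

## Heatmaps, pattern rule, HM score

Each ordered position pair (a₁×a₂, a₁×X, a₂×X) induces a partition of the
space into 400 groups of 20 motifs; cell = mean EF of its group, so the
unweighted mean of any heatmap's 400 cells equals the grand-mean EF
(asserted to 1e-9). For pattern calls the source procedure is ambiguous
about the interval construction; we compute, separately for rows and for
columns, the population SD of the 20 line means and set cutoffs at
grand mean ± z·SD with z = 1.96 (configurable; a t-based alternative can
be expressed through z). A residue is flagged when ≥ 18 of its 20 cells
lie *strictly* beyond a cutoff — cells exactly on the cutoff do not count.
The HM score of a motif is the sum of its three cells; with 8,000 motifs
this smooths single-motif outliers (raising one motif's EF by δ moves its
own HM score by exactly 3δ/20).

## Decision tree

Features are set-membership indicators per position over all residue
subsets of size ≤ 5 (65,097 features). The tree maximizes information
gain (binary entropy, bits) under max depth 3 and ≥ 50 samples at *every*
node (a split is infeasible if either child would fall below 50). Ties in
gain resolve to the first feature in enumeration order (position-major,
then subset size, then lexicographic), making fits deterministic; a
permuted feature order yields identical predictions on tie-free inputs.
Because each motif carries exactly one residue per position, a set
feature's count within any node is the sum of per-residue counts, so node
statistics for all features reduce to three 20-bin histograms and one
matrix product — the 8,000 × 65,097 matrix is never materialized.
Training labels binarize the EF table at a stated threshold (default
EF > 1, enriched vs depleted); the choice is logged in the model metadata
since the continuous-to-binary rule is not dictated by the data.
scikit-learn's entropy tree serves as an independent cross-check in the
test suite, never as the implementation.

## Synthetic screen

The generator states a world and keeps it fixed:

* **Ground truth** (rule-based propensity p ∈ [0,1]): p = 0 for charged
  a₂ (D/E/K/R); p = 0.45 for X ∈ {K,P,R} without the aliphatic a₂ rescue
  (I/L/M/V); p = 0.95 otherwise, +0.05 for Q at X. The 0.45 mid-level
  reflects partial residual activity of X-penalized motifs; the rescue
  reproduces the interaction the screen's tree discovers. Additive
  propensity noise is available but defaults to 0: noise clipped at 0
  biases the restricted class upward, which is a generator artifact, and
  multinomial read sampling already supplies realistic stochasticity.
* **Library**: lognormal abundance weights with σ = 0.447, putting the
  99.5th/0.5th percentile ratio near the ~10× imbalance observed in real
  trimer-codon libraries.
* **Growth**: weight(m) ∝ naive(m)·(1 + s·p(m))^G with G = 8 generations
  and s = 0.3 at 37 °C, s = 0 at 25 °C. The multiplicative form keeps EF
  analytically predictable (two motifs with p = 1 and p = 0 end at ratio
  (1+s)^G). With these defaults the noiseless EF dynamic range is
  (1.3)⁸ ≈ 8×, narrower than a real screen's extremes; saturation,
  PCR jackpotting and sequencing error beyond the quality model are not
  simulated. A green recovery test therefore establishes that the
  pipeline recovers planted rules at realistic depth and replicate
  structure — not that it reproduces any particular real screen's values.
* **Reads**: 8 replicates per condition, 5×10⁵ reads each, multinomial;
  FASTQ emission embeds the anchor, one fixed codon per amino acid, the
  downstream stop context, and per-base qualities (clipped normal,
  mean 37); 2% junk reads (anchorless, low quality) exercise the QC path.
  The per-replicate truth table records the exact draw, so extraction can
  be checked for exact round-trip identity.

## Numerical and edge-case choices

* EF requires nonzero totals in both conditions (hard error otherwise);
  quartile and top-fraction ties break by motif lexicographic order;
  quartiles are exact 2,000-member blocks.
* Confusion percentages: %correct over all rows; %FP over predicted
  positives; %FN over predicted negatives — the only convention consistent
  with the benchmark panel's printed summary block. Reported percentages
  round half-up to one decimal; raw fractions are kept in machine output.
* Classification is strict (score > cutoff); a score exactly at the
  cutoff is negative.
* The duplicated CKQH row in the benchmark panel is preserved — the
  printed totals require 48 rows — and the three doublet-gel motifs
  (CSGL, CSGK, CKQR) are encoded observed-negative.

## Known limitations

* The null-calibration property "mean EF within 3·SE of 1 under zero
  selection" sits exactly at the ratio-estimator bias of EF at the
  default depth: E[EF] − 1 ≈ E[1/n₂₅(m)] ≈ e^{σ²}/500 ≈ 0.0024, while
  3·SE ≈ 0.0023 with 8,000 motifs — a z-statistic of ≈ 3.1 by
  construction, independent of seed. At this depth the mean-EF clause
  fails in roughly half of the runs; the companion clause (no spurious
  heatmap patterns under the null) holds essentially always. Deeper
  sequencing (≳ 4×10⁶ reads per replicate) or a bias-corrected ratio
  estimator would be needed to center the mean; neither is part of the
  stated world, so the corresponding acceptance test is left failing with
  this analysis rather than retuned.
* EF point estimates carry no per-motif uncertainty; the package does not
  attempt variance estimation or significance testing of individual EFs.
* The C-terminal proteome scan is a local FASTA operation; census numbers
  against live databases are version-dependent and not reproduced.
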