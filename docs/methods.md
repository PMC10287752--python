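# Methods

This note documents the models and procedures implemented in
`editaudit`, their tunable parameters, the synthetic worlds the
generators emulate, and the numerical choices made where the design was
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Variant audit

**Normalization.** Variants are left-aligned and made parsimonious with
the usual extend-before-empty algorithm: while both alleles share their
last base, the representation is shifted left (prepending the reference
base when an allele would otherwise empty) and truncated; shared leading
bases beyond the one-base indel anchor are then trimmed. SNVs are fixed
points and the operation is idempotent. An indel pinned at the contig
start cannot shed its shared trailing base and is left at position 1;
the test oracle (exhaustive enumeration of equivalent representations)
encodes the same convention.

**Merging and support.** Call sets are merged per (chrom, pos, ref,
alt). Depths and allele frequencies for a tissue come from the
highest-priority caller reporting them there (WGS priority MU > HC >
LF/SC, RNA PL > HC > ST); when no caller reports depths the tissue is
*unmeasured*, a state distinct from a measured zero. A caller *supports*
a variant in a tissue only when its record carries evidence for the
alternative allele (alt depth > 0, AF > 0, or a bare call without
measurements); cohort-mode callers emit AF = 0 records for non-carrier
tissues, which contribute measurements but not support.

**Confidence filters** (defaults `min_callers=2`,
`min_depth_per_tissue=5`, `min_alt_total=2`): keep a variant iff ≥ 2
callers support it in at least one tissue, every tissue has measured
total depth ≥ 5 (a config switch `unmeasured_depth_passes` relaxes this
for single-sample-caller-only inputs), and alternative reads summed over
tissues reach 2. Raising any threshold is monotone (never grows the
kept set).

**Specificity.** Common variants (AF > 0 in every tissue) are labelled
on the whole quality-filtered set, *before* known-variant exclusion;
tissue-specific labels are assigned only within the novel pool and
require AF > 0 in exactly one tissue with 0/unmeasured elsewhere.
Everything else is `other`. The three labels partition the filtered set.

## Guide homology

The scanner reports, for a window (default ±30 bases around the variant
start, clipped at contig ends and scanned as-is), the minimum over both
strands and all placements of substitutions + gap events between the
20-nt protospacer and the window, with the PAM abutting the
protospacer's 3' end:

* gap events are single-base (the interface exposes `max_gap_len` but
  only 1 is supported), at most two per alignment, never adjacent
  within the same sequence (no multi-base gaps), and window-side bulges
  must fall strictly inside the protospacer;
* `strict` mode (default): the PAM must match its IUPAC pattern with
  zero edits; placements violating it are inadmissible. `lenient` mode:
  PAM mismatches are counted into the distance. Gaps are never allowed
  in the PAM;
* ties break by fewest gaps, then smallest offset, then the + strand;
* the seed region (PAM-proximal `seed_length`, default 12) is reported
  as a sub-count of edits; `forbid_seed_gaps=True` additionally
  disallows gap events inside the seed. Substitutions are allowed
  anywhere — with the stricter reading of the seed rule available
  behind the flag — because the source description of the constraint is
  ambiguous between "edits only in the seed" and "1-bp events anywhere
  but the PAM".

The implementation enumerates gap configurations over numpy prefix-sum
mismatch tables; the test suite checks it against an independent
explicit-state dynamic program on hundreds of random (window, guide)
pairs in both modes. Note that strict-mode distance can exceed
lenient-mode distance (strict may reject the lenient optimum); the
suite asserts lenient ≤ strict whenever a strict placement exists.

## Amplicon editing profile

Reads are consumed pre-aligned (strings over {A,C,G,T,-} of the window
length; alignment itself is out of scope). Replicate counts are summed
before any fraction is formed. *Repaired* = reads exactly equal to the
wild-type sequence over the quantification span (default: the whole
window) — bystanders, residual mutations, indels and sequencing errors
all disqualify, so the repaired fraction is a lower bound on the
on-target edited fraction, which is reported separately. Positions are
labelled in the guide frame (`<refbase>_<position>`, protospacer 1–20,
PAM 21–23, negative indices upstream, no position 0); PAM positions are
excluded from bystander counting. Codon consequences use the standard
genetic code on a caller-supplied frame. `min_frequency` (default 0 =
the raw metric) masks bystander positions at or below a noise floor.
The conditional table partitions reads by their base at the target
position; empty partitions yield an undefined (None) frequency, not 0.

## Splice rescue

ΔPSI values are group means (over non-missing replicates, minimum one)
minus the wild-type mean, taken from two pairwise junction-count
comparisons (treated vs WT, edited vs WT); the FDR is consumed from the
original comparison, never recomputed. The significance gate is strict:
FDR < 0.01 and |ΔPSI_original| > 0.1. For significant events with both
deltas (o = original, e = edited):

* `unchanged` if |o − e| < 0.1;
* for o > 0: `rescued` iff 0 ≤ e < o, or −0.2 ≤ e ≤ 0.2 and e < o;
  `mis-spliced` otherwise (e > o on the same side, or e ≤ −0.2);
* the o < 0 case is the mirror image.

The printed criteria make the rescued band and the mis-spliced
overshoot clause both true at |e| exactly 0.2; the classifier gives the
band (rescued) precedence — the unique minimal resolution under which
the three categories partition the plane for |o| > 0.1. The classifier
is sign-symmetric, so the ΔPSI sign convention (group − WT) does not
affect results.

## Activity score

Within a cluster, markers are chosen by a two-sided Wilcoxon rank-sum
test per gene between two conditions (p ≤ 0.05), split by the sign of
the mean difference, and capped at 15 per direction ranked by ascending
p with |mean difference| as tie-break (the ranking rule is this
package's choice; the source only caps the count). Scores min–max
rescale each marker across the scored cells and average over the set;
constant genes are dropped with a warning (an all-constant set is an
error). Scores are invariant to positive affine transforms of any
single gene. The threshold scan uses a 0.01 grid with strict ">" for
"above"; the critical threshold is the first grid point where the
downregulated condition (lowest mean score unless specified) falls
strictly below 50% active cells. PC distances: principal components via
eigendecomposition of the pooled, centered expression covariance,
component signs fixed by largest-loading positivity; each non-reference
cell is paired with every reference cell in the PC1–PC2 plane (an
`all_pairs` flag pools within-set pairs instead). Because the PCA is
refit on whatever subset is passed, duplicating a *subset* of cells
reweights the fit and can rotate the plane; distance values are exactly
preserved only under transformations that keep the fitted plane (e.g.
duplicating every cell).

## Synthetic worlds

All generators are deterministic under a fixed seed and return the
ground truth they planted; tests compare pipeline output against that
truth, never against hard-coded numbers.

* **Reference/plants:** uniform-random contigs; each planted site is a
  protospacer copy with exactly the requested substitutions and a PAM
  instantiated from the IUPAC pattern, on either strand; plants may not
  overlap. A planted distance is an upper bound by construction; with a
  valid PAM and random background it is the reported minimum for small
  k (asserted at k ≤ 3).
* **Caller outputs:** detection per variant with per-caller sensitivity
  (one draw for cohort callers, per-carrier-tissue for single-sample
  callers); depths Poisson(40 by default), alt reads Binomial(depth,
  true AF); germline AF 0.5/1.0 everywhere, somatic AFs uniform on
  [0.2, 0.5]; false positives uniform over the genome with Beta(1, 20)
  AFs. Germline keys populate the known-variant set. With the default
  uniform 6-class spectrum and uniform base composition, each collapsed
  conversion class is equally likely; for non-uniform spectra the
  marginal is only approximate because the alternative allele is drawn
  conditional on the reference base.
* **Amplicon reads:** repair (target transition A>G / T>C) with the
  stated probability; bystanders per position, on repaired reads only
  in conditional mode; single-base deletions inside the protospacer
  span; substitution-only sequencing error applied last. The truth
  records per-read flags and the model expectation of the
  exact-wild-type fraction, repair·(1−indel)·Π(1−bystander)·(1−error)^L.
  Because sequencing errors are observationally indistinguishable from
  edits, the *measured* bystander rate among unrepaired reads in
  conditional mode is not exactly zero but sits at the error floor
  (≈ error/3 for a specific base); the construction-level zero is
  asserted on the truth flags.
* **Splice tables:** deltas are drawn inside their category's region
  with ≥ 0.03 margins from every boundary and per-replicate jitter
  ±0.01, so replicate means cannot cross a boundary and label recovery
  is exact by construction.
* **Expression matrices:** per-gene baseline Normal(mu_g, sd = 0.5)
  with mu_g ~ U(1, 3), clipped at 0 (log-normalized-scale values);
  truth genes shifted by ±effect·sd in the mutant condition (`effect`
  is in sd units; 2 is the canonical "clear effect" setting).

A green test on these worlds establishes that the computations
implement their definitions and recover planted truth under realistic
noise; it does not establish performance on real caller outputs, whose
error modes (alignment artifacts, systematic caller disagreement,
strand bias) the simulators do not model.

## Known limitations

* The VCF layer reads only CHROM/POS/REF/ALT and the first sample's
  AD/DP/AF; other content is ignored (not round-tripped). Allele
  frequency round-trips at 1e-6 (VCF Float precision).
* Insertions in amplicon reads are not represented (deletions only);
  the per-position fraction table therefore sums to exactly 1.
* `max_gap_len > 1` in the homology scanner is not implemented; the
  admissible-alignment definition is single-base events.
* The pipeline is single-individual; multi-animal aggregation (e.g.
  mean ± SEM across mice) is limited to `summarize_mismatch_profile`
  style group summaries over externally provided labels.
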