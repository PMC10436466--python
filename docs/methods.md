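# Methods

## Scope and data model

The unit of observation is the clonotype: a unique rearrangement keyed
by CDR3 nucleotide sequence plus V/J gene calls, with a read count and
within-sample frequency. A sample (`Repertoire`) carries patient,
compartment (e.g. `initial`, `CD4`, `CD8`) and chain labels; a
`Cohort` groups samples by patient/biopsy and compartment. Analyses
that operate on amino-acid clonotypes use the collapsed view
(`AARepertoire`), in which nucleotide variants of one CDR3aa are
summed and the number of distinct variants is retained — collapse
precedes the length, physicochemistry and motif analyses, and
biopsy-slice samples are merged per patient before all comparative
analyses.

Tables are read and written in two dialects: VDJTools-style TSV
(`count freq cdr3nt cdr3aa v d j VEnd DStart DEnd JStart`, reference
points 0-based within the CDR3, `-1` = missing) and AIRR Rearrangement
TSV (`junction junction_aa v_call d_call j_call duplicate_count`, with
optional `*_sequence_*` offset columns carrying the same CDR3-local
coordinates). Missing reference points propagate as missing, never as
zero.

## Preprocessing

* **Productive filter** — a clonotype is excluded when its CDR3aa
  contains a stop (`*`) or frameshift (`_`) marker or its CDR3nt
  length is not divisible by 3. The frame rule is a proxy for the
  aligner's out-of-frame flag, which is unavailable downstream of the
  clonotype table.
* **Decontamination** — matched on (cdr3nt, V, J), a clonotype is
  removed from sample A when any other sample carries it at frequency
  ≥ `ratio` × its frequency in A. The default ratio of 20 follows the
  convention of the VDJTools ecosystem; the source analysis names the
  step but not its parameters, so both the ratio and the match key are
  configuration.
* Frequencies are renormalized after every filtering step and checked
  to sum to 1 within 1e-6.

## CDR3 features

The N(D)N region is `[v_end, j_start)` within the CDR3 — the
non-germline nucleotides (N-additions plus D remnant). Length
summaries report unweighted mean/SD over distinct clonotypes and a
frequency-weighted mean; N(D)N statistics use only clonotypes with
reference points present.

Physicochemical profiles score the central 5 residues of the CDR3aa
(window start `floor((L−5)/2)`; even-length ties resolve toward the
N-terminus — a fixed convention, since none is standard), normalize by
the window size, and weight by aa-collapsed clonotype frequency.
Sequences shorter than 5 aa are skipped with a logged warning and the
retained frequencies renormalized. Three scales are registered and
swappable: charge (K/R = +1, D/E = −1 at physiological pH, H neutral),
Kyte–Doolittle hydropathy, and a binary polarity indicator over
{N,Q,S,T,Y,C,H,K,R,D,E}. Published profile magnitudes depend on the
scale convention, so absolute values are comparable only within one
scale choice.

## Repertoire statistics

* **Diversity** — Shannon entropy `H = −Σ fᵢ ln fᵢ` (nats) over
  clonotype frequencies at nt level by default (aa level optional),
  normalized as `nS-W = H / ln S`. `S = 1` is defined as `nS-W = 0`
  (the maximally clonal limit; avoids 0/0). No rarefaction or depth
  normalization is applied — nS-W is depth-sensitive, which is a known
  caveat when comparing samples of very different size.
* **Convergent recombination** — `CR = Σ nt_variants / S ≥ 1` on the
  collapsed repertoire; a CDR3aa is *convergent* when ≥ 2 nucleotide
  rearrangements encode it. CR depends only on distinct-sequence
  counts, hence is invariant under count rescaling.
* **Publicity** — computed on patient-merged, aa-collapsed
  repertoires of one compartment; a CDR3aa is *public* when present in
  ≥ 2 biopsies (slice-level sharing within one patient never counts).
  The publicity × convergence cross-tab calls a sequence convergent
  when any single patient's merged repertoire carries ≥ 2 of its nt
  variants, so within-patient convergence is not conflated with
  cross-patient sharing.

## Motif clustering

Motifs are 3–7 residue patterns over the 20-aa alphabet with at most
one `%` wildcard (any single residue). Enumeration takes exact k-mers
(k ∈ {3,4,5}) and single-wildcard windows (length ∈ {5,6,7}) from the
CDR3 *interior* — the first 3 and last 2 residues, dominated by
germline V/J sequence, are excluded. The wildcard may occupy any
position except the last; a trailing wildcard adds no information
beyond its prefix, while a leading one (e.g. `%NYSNQP`) is a
legitimate discovered pattern.

Each motif is scored against a user-supplied background reference
repertoire (the synthetic module provides one; no human naive
reference is bundled):

* **Fisher score** — one-sided Fisher exact p of the 2×2 table
  [carriers/non-carriers × sample/reference], counting distinct aa
  clonotypes (collapse precedes motif analysis). Checked against an
  independent hypergeometric tail in the tests.
* **Expansion score** — permutation p-value (B = 1000, seeded) that
  the summed frequency of the motif's carriers exceeds that of random
  carrier sets of the same size. This is this package's own
  permutation formulation of the clonal-expansion idea behind
  GLIPH-style expansion scoring.
  Nulls are shared between motifs with equal carrier counts — the null
  depends only on the subset size — which makes scoring thousands of
  motifs tractable.

Motifs passing both thresholds (defaults 0.5/0.5, both configurable;
the source material is ambiguous about the inequality direction, and
since both scores are p-value-like, smaller = stronger, the thresholds
are upper bounds) become clusters of all matching sample sequences.
Exact motifs fully contained in a passing longer motif with an
identical carrier set are suppressed as redundant. At the default 0.5
thresholds roughly a quarter of tested motifs pass by chance; the
thresholds are deliberately permissive, and downstream interpretation
rests on sharing across biopsies and database annotation rather than
on the raw pass count. Not implemented: global Hamming-similarity
clustering, V-gene bias and HLA scoring, CDR3-length-distribution
scores.

A calibration note: the Fisher score is well calibrated over the set
of motifs with ≥ 1 sample carrier (the scoring precondition).
Conditioning the tested set on ≥ k carriers selects upward-fluctuated
motifs and the pass fraction among them exceeds the nominal level even
under a pure null; the null-calibration check therefore uses the full
scoreable universe.

## Annotation

Candidate sequences come from three (overlapping) sets over a
compartment's pooled aa universe: frequency > 0.1%, public, and
motif-clustered. They are matched against a specificity database
(`cdr3aa, category ∈ {allergy, autoimmunity, cancer, pathogens},
source`) at Levenshtein distance ≤ 1 (edlib; length pre-filter
|Δlen| ≤ 1 before distance computation; matching is CDR3aa-only, with
no V-gene or chain-pairing constraint). A cluster member with a direct
cancer match marks all other members of its cluster as putatively
tumor-associated (`propagated`); matches in other categories are
recorded but not propagated by default (configurable). A sequence
matching several categories keeps all of them.

## Statistical layer

`compare_groups` dispatches four designs — one-way ANOVA + Tukey HSD,
paired t, two-way ANOVA with Šidák-adjusted pairwise contrasts of the
primary factor within secondary-factor levels, and Pearson r — backed
by scipy/statsmodels. Missing values are dropped pairwise with the
count reported; degenerate inputs (groups < 2, zero variance where
the statistic needs it) raise instead of yielding NaN. Identical
pairs in the paired design return (t = 0, p = 1). Normality is not
tested before the parametric tests, matching common practice in this
kind of analysis; treat small-sample p-values accordingly. No
multiple-testing control is applied across panels.

## Synthetic cohorts

The generator produces repertoires with the canonical `C...F` CDR3
structure from a toy germline of 8 V and 6 J CDR3 flanks (hardcoded,
preferred-codon-encoded; no attempt at realistic gene-usage
frequencies or thymic selection). Per clonotype: V and J flanks are
drawn uniformly, an N(D)N of Gaussian length (rounded, truncated at 0)
is filled with uniform nucleotides, the V end is trimmed 0–2 nt to
keep the junction in frame (so the planted N(D)N length is preserved
exactly), and stop-codon draws are rejected. CDR3aa sequences are kept
distinct within a repertoire, which makes translation consistency and
variant counting exact.

Knobs and their planted effects:

* `ndn_length_mean/sd` — junction length; presets use 14.4 ± 3.1 nt
  (CD4-like), 11.4 ± 2.2 (CD8-like), 13.8 ± 2.1 (initial).
* `charge_bias` — each central-5-mer residue is replaced by K/R
  (positive bias) or D/E (negative) with probability |bias|; presets
  +0.06 / −0.04 / −0.01. The realized profile shift sits on top of the
  baseline composition (uniform nucleotides slightly favor arginine,
  so the baseline is mildly positive).
* `clone_size_law` — geometric counts, or a rank-frequency power law
  whose exponent is solved (Brent) so the ideal law's nS-W equals a
  target; presets target 0.38 / 0.51 / 0.45. Counts are then drawn
  `1 + multinomial`, so realized per-sample diversity scatters around
  a value slightly above the target; group ordering is what the
  presets guarantee.
* `convergence_rate` — probability that an aa clonotype gains one
  synonymous nt variant (one codon swapped); preset 0.05, giving CR
  levels near 1.05.
* `planted_motifs` — motif residues are codon-substituted into a
  random interior position of carrier CDR3s (wildcard positions get a
  random residue per carrier); carrier clones are expanded 5× (motif
  clusters model antigen-selected, expanded clones — without
  expansion the expansion score would be uniform and the joint filter
  could not select planted motifs). Motifs that cannot fit in the
  feasible interior are rejected with an error.
* `nonproductive_rate` — stop-codon or 1-nt-frameshift clonotypes to
  exercise the productive filter.
* Cohorts inject public CDR3aa into exactly the requested number of
  patients (first slice, all compartments, two synonymous variants —
  public clones tend to be convergent) and emit a neutral background
  reference repertoire for motif scoring.
* Unsorted initial cultures are CD4/CD8 mixtures at a per-patient
  composition, which is what makes diversity correlate inversely with
  the CD4+ fraction.

What the generator does **not** emulate: sequencing error, UMI/depth
effects, real gene-usage and junctional-insertion distributions,
HLA-driven selection, or TRA/TRB pairing. Passing tests therefore
demonstrate that the pipeline recovers planted statistical structure
of the kinds listed above — not that it would reproduce any particular
study's numbers on real data, which also depend on the deposited
samples and the live database version.

## Study-scale conditions and numerical choices

Parameter-recovery experiments use 20 replicate cohorts of 8 patients
per group, 2 slices × 2000 clonotypes per sample, compared on
patient-merged samples with paired t-tests at α = 0.05 — merging
slices is the same convention the comparative pipeline applies, and it
keeps the frequency-weighted charge profile from being dominated by a
single top clone. Motif recovery plants a 7-mer wildcard motif in 15%
of a 200-sequence sample against a 2000-sequence 1% background.
Type-I calibration runs 1000 null replicates per design. Determinism
is checked by byte-comparing two runs of the demo pipeline config.

Floating-point policy: frequencies serialize with 10 significant
digits (diff-stable roundtrips); report tables use `%.8g`; diversity
and profile computations are validated against independent
accumulation at 1e-12. All randomness flows from explicit integer
seeds through `numpy.random.Generator`; child seeds are drawn below
2³¹.
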