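# Methods

This note records the model, the conventions and the genuinely open design
choices behind `famhotspot`, in the spirit of a statistical software methods
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model and procedure

The unit of analysis is a protein family: a set of human protein sequences
(optionally trimmed to a shared Pfam-style domain) aligned into a common
column frame. Somatic single-residue substitutions, read from a tab-separated
MAF derivative, are remapped from protein coordinates to consensus columns;
pooled per-column counts n_i (total N) are then tested against a random-
placement null.

The null is a bootstrap (default 1000 replicates, as many as the method
needs for stable Gamma fits at desk scale): each replicate places N
mutations multinomially over the K columns with probabilities proportional
to per-column residue coverage. Coverage weighting matters — without it,
gappy alignment edges would look artificially quiet and conserved cores
artificially hot.

Two tests are run:

* **Global.** Shannon entropy H of the observed count frequencies versus the
  bootstrap entropy distribution. A Gamma distribution supplies the
  parametric null; the p-value is P(H_null ≤ H_obs), since clustering can
  only lower entropy.
* **Per position.** For each column, a Gamma fitted to that column's
  bootstrap counts gives p_i = P(X ≥ n_i). Columns whose Trident
  conservation exceeds 0.1 (strict) enter Benjamini–Hochberg correction;
  the hotspot call is q < 0.05. Unconserved columns keep their p-value but
  get no q, so nothing disappears silently — a mutation count on an
  unconserved column is simply not comparable across members.

## Orientation of the global Gamma null

The bootstrap entropy distribution is bounded above by ln min(N, K) and is
left-skewed, while a Gamma density is right-skewed; fitted directly to H,
the Gamma systematically misestimates the lower tail, which is exactly the
tail the test uses. The package therefore fits the shifted three-parameter
Gamma to the entropy deficit D = ln min(N, K) − H — non-negative,
right-skewed, the natural orientation for a Gamma — and computes the global
p-value as the fitted upper tail in D. This is the same lower-tail-in-H
test, just parametrized so the Gamma family can actually represent the
null; the calibration experiment in the acceptance suite measures the
resulting uniformity of null p-values directly.

Zero-entropy replicates (all N mutations on one column, possible at very
small N) sit at the deficit's support edge and are excluded from the fit;
if more than 10 % of replicates are zero-entropy the parametric fit is
abandoned for the smoothed empirical tail (1 + #{H_boot ≤ H_obs}) / (B + 1).

## Gamma on discrete, zero-inflated counts

Per-column bootstrap counts are small integers with many zeros, while the
Gamma lives on (0, ∞). The rule set, chosen once and applied everywhere:

* n_i = 0 → p = 1 (no evidence, no fit needed); a zero-weight (all-gap)
  column gets p = 1 with a diagnostic, since such a mutation is unmappable.
* If more than 90 % of a column's bootstrap counts are zero, the Gamma is
  skipped and the smoothed empirical exceedance
  (1 + #{boot ≥ n_i}) / (B + 1) is used. Including the observed point mass
  and adding one keeps the p-value strictly positive and monotone in n_i.
* Otherwise the Gamma is fitted to counts + 0.5 (continuity offset moving
  the support off zero) and evaluated as the upper tail at n_i − 0.5.

Gamma fitting is maximum likelihood with moment-matching initialization and
Newton iteration on the profile likelihood in the shape parameter; the
per-column fits are vectorized across columns, which is what makes
hundreds of replicate analyses per minute possible. Constant bootstrap
columns (zero variance) fall back to the empirical rule; `fit_gamma`
returns an explicit degenerate marker rather than fake parameters.

## Conservation scores

Trident per column: score = (1−t)^α (1−r)^β (1−g)^γ with defaults
(α, β, γ) = (1, 0.5, 3), the weighting recommended by the original Trident
scoring work; all three exponents are configurable. t is the symbol entropy
of the non-gap residues normalized by ln min(20, n); r is the mean pairwise
BLOSUM62 distance, where similarity is first normalized Karlin-style
(s(a,b)/√(s(a,a)s(b,b))) so every identical pair scores distance 0, then
rescaled so the most dissimilar canonical pair scores 1; g is the gap
fraction of the whole column. Entropy and the chemical term use non-gap
residues only, the gap term uses all rows — a convention, flagged as such.
An all-gap column scores 0 with g = 1.

The k-tuple homogeneity check uses k = 3 (tripeptides, the common choice
for protein k-tuple distances; the measure's k is not dictated by anything
upstream): shared distinct k-tuples over the distinct k-tuples of the
shorter sequence. A member whose mean similarity to the rest falls below
0.2 is named in a warning; the analysis proceeds regardless, because the
check is a safety net against accidentally mixed families, not a filter.

## Alignment and coordinates

All public protein positions are 1-based inclusive (a "G12" mutation sits at
position 12); consensus columns are 1-based in every report. Alignment rows
must degap exactly to the input sequences — this is enforced, not assumed.
Domain-trimmed members carry a fragment offset so mutation records can stay
in full-protein coordinates. Consensus ties break to the alphabetically
first residue (a documented convention; nothing upstream specifies an
order), and a gap never becomes consensus while any residue is present.

Three alignment backends: a precomputed aligned FASTA; an external
clustal-omega-compatible executable; and a builtin deterministic center-star
progressive aligner (BLOSUM62, affine gaps, gap open −10 / extend −0.5)
whose pairwise steps use Biopython's `PairwiseAligner`. The builtin aligner
exists so the test suite and examples never require an external binary; it
is deliberately not a Clustal Omega reimplementation, and its use is logged.
Subsetting members never re-compacts columns, so hotspot positions from a
subfamily analysis remain comparable with the full-family frame.

## Co-occurrence model

For features a and b with n_a and n_b mutated samples among n sites, the
co-mutated count J under random placement is hypergeometric; both tails
include the observed point mass (so p_lt + p_gt ≥ 1). Tail p-values are BH-
corrected across all pairs within a tumor-type stratum by default
(configurable to none/Bonferroni; the choice of correction across pairs is a
package decision, nothing upstream names one). Pairs with expected
co-occurrence below 1 are flagged low-power rather than suppressed. The
Fisher 2×2 test reports the sample odds ratio with explicit inf/nan
conventions for degenerate cells.

## Synthetic data: what it emulates, what it does not

The generator produces an ancestral random sequence, independent per-member
substitutions (default rate 0.15 — a coherent, moderately diverged family
that does not trip its own homogeneity safety net) and deletions relative to
the ancestor (default 0.03), returning the exact true alignment in ancestral
coordinates. Cohorts place a chosen fraction of mutations on planted
consensus columns (member chosen uniformly among those covering the column)
and the rest uniformly over all residues; samples carry tumor-type labels,
and gene pairs can be forced mutually exclusive by rejection sampling.
Mutation totals derive from a per-sample Poisson background unless pinned
explicitly with `total_mutations` (required when everything is hotspot).

Deliberately absent: insertions (the true alignment stays in ancestral
coordinates), phylogenetic correlation between members, trinucleotide
mutational signatures, isoform ambiguity, and any gene-length or
expression covariates of real mutation rates. Passing tests therefore
demonstrate the statistical machinery under its own model assumptions —
correct calibration, power and bookkeeping — not robustness to the full
messiness of real cohorts.

## Experiment problem sizes

The packaged experiments (`famhotspot.experiments`, shared by the acceptance
tests and `scripts/acceptance.py`) use: 500 replicate runs at K = 100,
N = 50 for null calibration; 200 runs for power against a planted hotspot
carrying 30 % of mutations; 100 runs each for the rescue and silent-control
scenarios; 10 000 draws for Gamma recovery and bootstrap-moment checks.
These sizes give rate estimates with standard errors of a few percent while
keeping a full pass in the low minutes.

The rescue scenario uses 12 members of length 60: with N = n_members
mutations over K ≈ length columns, the per-column bootstrap zero fraction
(1 − 1/K)^N must stay below the 0.9 empirical-fallback threshold for the
Gamma tail to resolve far-tail p-values; at 12/60 it does, so the planted
column can survive BH correction over ~60 gated columns, which is the point
of the scenario.

## Known limitations

* The builtin center-star aligner is adequate for closely related families
  and tests, not a production MSA tool; use an external aligner or a
  precomputed alignment for real analyses.
* Per-position p-values inherit the bootstrap's granularity: with B
  replicates the empirical fallback cannot go below 1/(B+1), so very rare
  events need the Gamma branch (i.e., enough mutations for most columns to
  see nonzero bootstrap counts).
* Only single-residue substitutions are position-parseable; in-frame indels
  are skipped with diagnostics, and DNA-level recurrent events are invisible.
* The mutual-exclusivity model conditions on marginal counts and assumes
  exchangeable samples within a stratum; strong mutation-burden
  heterogeneity between samples can mimic co-occurrence.
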