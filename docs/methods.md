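# Methods

This note documents the models, the numerical choices, and what the
synthetic fixtures do and do not establish.

## Coordinates and strand symmetry

All coordinates are 0-based half-open (BED convention). A breakpoint is
a *bond* — the backbone position b between base b−1 and base b on the
plus strand — with no strand attribute, since a double-strand break
severs both strands at essentially the same place. A bond is considered
inside an interval [s, e) when either of its flanking bases is, i.e.
when s ≤ b ≤ e; blacklist subtraction removes bonds at both interval
edges under this rule.

Every k-mer quantity is computed on canonical forms (the lexicographic
minimum of a k-mer and its reverse complement): for even k there are
(4ᵏ + 4^(k/2))/2 classes (32,896 octamers), for odd k exactly 4ᵏ/2.
k-mers containing N are skipped from all counts. As a consequence every
score, feature and scan output is invariant under reverse
complementation of its input — with one deliberate exception handled
below (GC skew).

## Range of influence

The positional profile tallies, per chromosome, the canonical k-mer
starting at offset d ∈ [−W, W] from each breakpoint bond (default
k = 8, W = 500, i.e. a 1 kb window; breakpoints lacking W + k context
are skipped and counted). Per-offset counts are normalised to the
offset's total. Adjacent offsets are compared by RMSD over the full
canonical vocabulary, per chromosome, then averaged unweighted across
chromosomes; the curve's abscissa is the midpoint between the compared
offsets. The RMSD is invariant to vocabulary ordering by construction.

The curve is modelled as a constant baseline plus up to three zero-mean
Gaussians, fitted by bounded nonlinear least squares (σ bounded inside
the window, amplitudes non-negative). Because convergence is sensitive
to starting values, a grid of starts is used: σ starts
{2, 5, 10, 25, 50, 100, 250} bases (filtered to the window), crossed
with amplitude starts {0.25, 0.5, 1.0} × (peak − baseline); the
baseline is initialised at the median of the outer 10% of offsets —
without the baseline term, σ estimates inflate to absorb the noise
floor. A fitted component set is rejected, forcing a refit with one
fewer component, when any of: the fit did not converge; a component's
peak fraction is below 5%; an amplitude is zero; a σ is zero. Among the
acceptable component counts the best SSE wins, with near-ties (within
1% relative SSE, plus 10⁻⁹ of the curve's total variance to absorb
exactly-zero residuals) resolved toward fewer components — a noiseless
single-Gaussian curve fits exactly at any m by splitting the peak, and
the parsimonious answer is the meaningful one. A flat curve returns a
baseline-only fit with zero components.

A component's contribution is its peak amplitude as a fraction of the
summed peaks — deliberately *not* area under the curve, which would let
a shallow wide component dwarf a sharp narrow one despite the
biological weight of the immediate breakpoint context. Its span is the
95% CI width of the zero-mean Gaussian, 2·1.96·σ, in bases.

Spans pooled across samples are log2-transformed and Ward-clustered
(Euclidean) into three groups, ordered by mean span, to give the
short / medium / long labels; with fewer than three distinct spans a
fixed log-scale fallback is used (cutpoints 40 and 250 bases, between
the characteristic ~14 / ~72 / ~474-base windows). Sample-level RMSD
curves are clustered the same way (Ward/Euclidean), with silhouette
scores reported over a user-chosen range of cluster counts.

## k-meric susceptibility

Control regions are flanks placed beyond the reach of sequence
influence: width w = long-range span + 1000 bases when a span is known,
otherwise the mean length of the top-5% longest merged breakage
regions; the flanks occupy [s−2w, s−w) and [e+w, e+2w) around each
merged breakage region [s, e), clipped to the chromosome and with any
residual overlap with breakage regions subtracted.

The z-score is the one-sample proportion test of the case count Xᵢ
against the control proportion pᵢ with n = Σ Xᵢ trials (the only
reading under which the statistic is a valid proportion z). k-mers
violating the normal approximation — min(n pᵢ, n (1 − pᵢ)) < 5, or
pᵢ = 0 — are flagged and imputed as the mean z of the five nearest
non-flagged k-mers by Hamming distance on canonical forms, taking the
minimum over the two strand alignments, ties broken lexicographically;
fewer than five donors triggers a global-mean fallback with a warning.
The Bayes posterior uses the control relative frequency for P(kmer),
the case relative frequency for P(kmer | break), and a prior defaulting
to n_case / (n_case + n_control); posteriors are clipped to [0, 1] with
a warning when the likelihood ratio exceeds the prior's bound.

Score tables are standardised per sample (mean 0, sd 1) before
Ward-clustering samples and k-mers; constant tables are excluded.
Outlier analysis takes the per-k-mer difference of group means and the
⌈0.5%⌉ tails each side (165 octamers per set), compared by a
two-sample t-test on hybridization energies when a 64-triplet energy
table is supplied — a k-mer's energy is the mean of its overlapping
triplet energies (one-nucleotide sliding window). Cross-sample
correlation networks keep signed Pearson r with |r| ≥ 0.7, diagonal
removed, zero-variance tables excluded.

## Features

Feature windows are nested and centred on the bond: short 14, medium
72, long 474 bases (even-rounded defaults of the characteristic
windows). Per score table: the z of the canonical k-mer centred on the
bond (the octamer for k = 8; 0 when the window contains N), and the sum
of z over all sliding canonical k-mers of the long window. Long-range
composition: G+C content and the *magnitude* of GC skew |G−C|/(G+C) —
the signed skew defined by the field flips under reverse
complementation, so the matrix stores its magnitude to keep the
strand-symmetry guarantee; `composition_features` still returns the
signed value. Raw canonical k-mer counts over the long window default
to triplets (k = 3), with pentamers (k = 5) the intended alternative
for a generalised configuration. Medium range: putative G-quadruplex
density, matching G-runs ≥ 3 separated by 1..7-base loops, searched
with both the G-pattern and the C-pattern (i-motif mirror) on the same
strand; density is union coverage over the window.

Control bonds are sampled (seeded) at a 61:39 control:case ratio —
mirroring the deliberate class imbalance of real negative-control
sampling — from the admissible pool *after* excluding every bond whose
medium window could overlap a break's medium window; long-range overlap
is tolerated, as the signal beyond the medium span is negligible.
Explicitly provided control bonds pass through the same overlap filter.
Assembly is fully deterministic given the seed.

## Classifier, calibration, downstream maps

Two model kinds: logistic with L2 penalty and LightGBM. Hyperparameters
are drawn by seeded random search from fixed ranges — logistic: C in
1e-2..1, tolerance 1e-6..1e-3, iterations 100..1000; LightGBM: alpha
and lambda 1e-8..10 (log scale), leaves 2..100, learning rate
0.001..0.1, estimators 1000..10000, feature and bagging fraction
0.1..1.0 — maximising cross-validated AUROC inside a stratified 70/30
train/test partition, then refit on the full training split. LightGBM
runs single-threaded and deterministic; feature importance is split
gain (split counts dilute the informative score features across many
weak count features), logistic importance is |coefficient|.

Evaluation reports the full ROC, AUROC, and the confusion matrix at the
default 0.5 threshold (probability ≥ 0.5 calls positive, ties
inclusive). FPR calibration inverts the empirical step function of
negative scores without interpolation: the smallest cutoff whose
empirical FPR does not exceed the target, so the calibration-set FPR is
guaranteed ≤ target and lower targets never yield lower cutoffs;
targets below the 1/#negatives resolution warn and return a cutoff just
above the highest negative score.

Scans N-pad the sequence so edge bonds have a full long-range window
and evaluate interior bonds from max(1, stride/2) in steps of stride —
stride 1 is per-base, stride = length gives one central evaluation.
Fragility zones bin call densities into non-overlapping windows
(defaults 1,960 / 10,000 / 20,000 bases) and label the top 5% high and
bottom 5% low, ties resolved by (density, chromosome, start); fewer
than 20 bins is an error. SV delta fragility counts predicted calls
(not mean probabilities; a flag-level alternative was considered and
call counts chosen for interpretability as "breaks gained/lost") over a
1,960-base window centred on the variant before and after applying
REF→ALT, re-centred on the replacement; 1-base REF/ALT pairs get a
single centred evaluation.

Model persistence is a versioned JSON manifest (kind, feature names
with checksum, thresholds, seed, hyperparameters) plus a native text
blob (LightGBM model text, or logistic coefficients as JSON).

## Synthetic fixtures and what they show

The generator plants a per-canonical-octamer relative propensity
(log-normal exp(N(0, sd)), a fixed-motif boost, or uniform for the
null) and places breakpoints with probability proportional to
baseline + Σᵣ weightᵣ · (Gaussian(σᵣ)-smoothed propensity track), the
track evaluated at the octamer centred on each bond; sampling is
without replacement (Gumbel top-k), and σ = 0 is the short-range limit
in which the bond's own octamer decides. Defaults: GC 0.41, sigmas
(3, 30, 200), weights (0.6, 0.3, 0.1), baseline 0.2. Count-table
fixtures draw control counts multinomially from a background octamer
distribution and case counts from background × propensity.

One genuine physical subtlety: adjacent-offset RMSD measures the
*gradient* of the conditional composition around the breakpoint, so a
smooth placement envelope (σ > 0) yields a curve that dips at the
centre and peaks near ±σ — no central peak. The characteristic central
peak of real breakage data reflects breaks sitting at deterministic
positions relative to their sequence determinants (enzymes cut at fixed
motif offsets). The positive-control fixtures therefore use
motif-anchored breaks in the σ = 0 limit, which produce a strong
central peak (tens of MADs above the outer-decile noise floor at 2,000
breaks on 200 kb), while uniform controls stay within the noise.

Desk-scale study conditions used by the test suite and the acceptance
script: 200 kb genome; 2,000 breakpoints; z-tables estimated from
5×10⁶ case / 5×10⁷ control multinomial observations (direct octamer
counting from 2,000 breakpoints cannot exceed the insufficiency
threshold at 32,896 classes — the multinomial tables play the role of
the genome-scale counts real studies have); end-to-end fixture with
log-normal sd 2.5, baseline 0.1, short-range limit; training matrices
of ~5,100 rows with a search budget of 3 and 2-fold internal CV. Under
those conditions the gradient-boosted model reaches held-out AUROC
≈ 0.96 with the score-table features carrying most of the top-20 gain.

What the fixtures do **not** emulate: chromatin and epigenomic
structure, mappability artefacts, repeat content, read-level noise, and
correlated octamer propensities (real fragility scores vary smoothly in
sequence space; planted ones are i.i.d.). Passing tests therefore
demonstrate correctness of the computations and recoverability of
planted sequence-intrinsic signal, not performance on real genomes.

## Known limitations

* The RMSD pipeline defaults to k = 8 for a single curve; pooling of
  several k sizes into one curve is not implemented (each k can be run
  separately).
* DNA shape parameters, stem-loop energies, heat-of-formation and
  epigenome-derived scores are consumed only as user-supplied per-k-mer
  TSV tables in the score-table interchange format; nothing is
  computed from structure.
* The hyperparameter search is random, not Bayesian; with the small
  budgets used here the difference is immaterial, and the search space
  is identical.
* Imputation distance is Hamming on canonical forms; gapped or
  alignment-based similarity is out of scope.
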