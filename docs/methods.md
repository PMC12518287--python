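# Methods

This note documents the models, defaults and numerical choices behind
`digeflow`, and what the synthetic-data validation does and does not
establish.

## Design and data model

The experimental unit is a gel channel: one organ (shoot or root), one
condition (control, anoxia, re-aeration), one biological replicate.
The default design is 3 conditions × 3 replicates per organ; organs are
analyzed as independent tables throughout. The `SpotTable` matrix holds
non-negative fluorescence intensities with missing spots carried as
explicit NaN — never as zeros — and flags recording whether the matrix is
log2-transformed and quantile-normalized. Gel-quantification software does
not document how spots absent from one gel are encoded, so missingness
policy is this package's choice: downstream statistics drop a spot's
missing samples pairwise, and a condition with no observation at all for a
spot is an error rather than a silent zero.

## Normalization

Intensities are log2-transformed. Zeros are replaced by half the smallest
positive value in their column (flagged with a warning); spots with no
positive value anywhere are excluded. Technical duplicates — columns
sharing (organ, condition, replicate) — are averaged on the log2 scale.
Quantile normalization forces every column onto the mean of the column
order statistics; ties receive the average of the order statistics they
span, so within-column rankings are preserved and the procedure is
idempotent. With missing values, ranks are computed over the observed
entries of each column and mapped through the mean quantile function on a
mid-point grid; this is approximate (column means are then only nearly
equal) and is flagged.

## Per-spot tests

**Kruskal–Wallis**: tie-corrected H with the chi-square reference on k−1
df. At 3 observations per condition the permutation support is tiny (1680
rank arrangements), so p-values are discrete with a smallest attainable
value ≈ 0.027. Consequences documented by the suite: p-values cannot be
uniform under the null in the Kolmogorov–Smirnov sense (the test is valid
but conservative), and BH adjustment over tens of spots cannot reach
0.05 — the rank test is essentially powerless at this design size.

**Mixed model**: y = condition fixed effects + replicate random intercept
+ error. The REML criterion is profiled down to the single variance ratio
λ = σ²_b/σ²_e, minimized by golden-section search on [0, 10⁴] (relative
tolerance 1e-8, floored at 0). The condition effect is tested by a Wald F
with denominator df n − p − (q − 1) when λ̂ > 0 (q = number of replicate
levels) and n − p when λ̂ = 0, in which case the model degenerates to
ordinary least squares and the test reduces exactly to the one-way ANOVA
F. Whether the random factor should be the biological replicate or the gel
is ambiguous in practice; the replicate id is the default and the factor is
a parameter. Layouts where the random factor is confounded with condition
are rejected as non-identifiable.

**Moderated F**: per-spot one-way fit; residual variances shrunk toward a
prior, s²_post = (d₀s²₀ + d_g s²_g)/(d₀ + d_g); moderated F compared to
F(k−1, d_g+d₀). The hyperparameters are estimated by moment matching of
e_g = log s²_g − ψ(d_g/2) + log(d_g/2): the trigamma equation
ψ′(d₀/2) = Var(e) − mean ψ′(d_g/2) is solved by Newton iteration
(tolerance 1e-8, 100-iteration cap), and s²₀ = exp(ē + ψ(d₀/2) −
log(d₀/2)). When the spread of log-variances is at or below its sampling
floor the prior df are infinite and s²_post = s²₀ everywhere; note s²₀
then carries the chi-square log-bias factor exp(log(d/2) − ψ(d/2)), which
is the reference behavior of the Bioconductor implementation this module
is cross-checked against (one unit test drives `Rscript`/limma on a toy
matrix and compares d₀, s²₀, F and p).

**Adjustment and selection**: BH (step-up) and Holm (step-down), monotone
and capped at 1; "FDR" is accepted as an alias of BH since the two names
denote the same procedure. Significance defaults to BH-adjusted p < 0.05
under the moderated test; the threshold, adjustment and test are all
configurable. Over-representation of a category among selected items uses
the one-sided Fisher exact test on the 2×2 table within a stated universe.

## Clustering and concordance

Sample and spot distances are Euclidean on normalized log2 intensities (a
choice, configurable). k-means uses k-means++ with 10 restarts and a fixed
seed; the elbow k maximizes the discrete second difference of the WSS
curve, which is also returned so a human can override the automated choice.
Hierarchical clustering is complete linkage; its k maximizes the mean
silhouette width over cuts k = 2..min(8, n−1), ties to the smallest k.

Concordance between partitions: for each cluster of the partition with
more clusters (ties favor the first argument), take the maximal Simpson or
Jaccard coefficient against the other partition's clusters; divide the sum
by the larger cluster count. S = 1 for identical partitions in both modes;
Simpson-S = 1 whenever the finer partition is nested in the coarser. The
traversal convention means swapping the arguments can change S slightly
even at equal cluster counts; relabeling clusters never does.

## Trajectory classification

Comparisons on the intensity scale use a relative tolerance δ (default
0.05; a 5% change counts as flat): a >δ b iff a > b·(1+δ). Decision
order: anoxia strict maximum → group 2; anoxia strict minimum → group 4;
non-increasing C ≥ A ≥ R → group 1; otherwise group 3. The rule is total,
scale-free, and reproduces the published qualitative description of each of
the 21 annotated significant proteins bundled with the package (the
curated table encodes those descriptions as mean triples on a common
arbitrary scale; the group label is *not* stored — it is recomputed by the
classifier every time). The condition-of-maximum label breaks exact ties
in C > A > R priority order. The boundary between "slight decline
everywhere" (group 1) and "dip with re-aeration recovery" (group 4) is
δ-dependent; published descriptions do not quantify it, so δ is exposed.

## Synthetic data

Spot intensities follow a log-normal model: log2 intensity = base (10) +
group sign-pattern × effect (2 log2 units) + N(0, noise_sd = 0.1) per
replicate, exponentiated back to fluorescence-like units. The sign
patterns ((+1,−½,−1), (−½,+1,−½), (−1,+½,+1), (+½,−1,+1) for groups 1–4
over C/A/R) are chosen so that noise-free data classify exactly into their
groups and anoxia profiles sit nearer re-aeration than control, matching
the qualitative sample-clustering observation the generator is meant to
emulate. Defaults (3×3 design, 15–20 spots/group, effect 2, noise 0.1)
are the validation conditions used by the test suite and acceptance
script.

Promoters are i.i.d. base sequences with P(A)+P(T) = at_fraction (default
0.6 — upstream regions are AT-richer than coding sequence in this genome);
motifs are instantiated from IUPAC consensi, placed non-overlapping by
rejection sampling (capped retries), on a uniformly random strand, with
positions recorded as ground truth. MS1 peak lists are the union of
tryptic peptide monoisotopic masses of a target and a contaminant protein
plus uniform noise peaks on the 700–3500 Da scan window.

What the generator does **not** emulate: gel warping and dye bias,
spot-detection errors, correlated replicate structure beyond the random
intercept, dinucleotide composition or positional structure of real
promoters, and MS/MS fragmentation. Passing tests therefore establish the
correctness of the downstream arithmetic and the internal consistency of
the pipeline under its own model — not the biological fidelity of any
upstream quantification.

## Protein physicochemistry

Residue masses: standard monoisotopic and average tables plus one water;
fixed carbamidomethyl-Cys (+57.02146 Da) applies to peptide masses (it is
the standard alkylation in the wet protocol), optional [M+H]⁺ (+1.00728)
for singly-protonated MALDI peaks, optional variable Met oxidation
(+15.99491) as extra candidate masses. pI solves Z(pH) = 0 by bisection on
[0,14] to 1e-3; Z is strictly decreasing because the termini are always
ionizable. The EMBOSS pKa set is the default with Bjellqvist selectable —
both are in wide use and pI values differ by a few tenths of a pH unit
between them. Gel MW from Rf interpolates linearly in (Rf, log10 MW)
between ladder anchors; values outside the anchor range are extrapolated
and flagged. The bundled protease sequence for autolysis-filter demos is a
constructed, trypsin-like *synthetic* stand-in (so labelled); real
analyses should supply their protease's reference FASTA. The autolysis
filter removes peaks within ±0.8 Da (the MS1 matching tolerance) of any
contaminant mass and returns the removal log.

## Promoter scanning

Upstream coordinates are 1-based negative offsets, −1 adjacent to the
annotated gene start. Extraction is strand-aware (minus-strand promoters
are reverse-complemented) and truncation at contig edges is flagged. IUPAC
matching is exact over degeneracy classes with overlapping hits reported;
PWM hits score log-odds against a uniform background with a default
threshold of 80% of the maximal achievable score (configurable — published
site databases do not state their thresholds, and overlapping sites are
deliberately not collapsed). Minus-strand hits are mirrored into the
promoter frame so `start` is always the leftmost matched base. Family
summaries count over an explicit gene universe with zeros included, so
families without hits are still reported.

## Known limitations

- The three-condition time axis has one point per phase; no smoothing or
  time-course modelling is attempted.
- The mixed model fits a single variance component; gel-by-dye effects and
  array weights are out of scope.
- Pairwise (contrast-specific) moderated tests are not provided — the
  omnibus condition effect is the published quantity of interest.
- The Kruskal–Wallis route is retained for completeness but is documented
  as underpowered at 3 replicates; conclusions should rest on the
  moderated test, as the analysis scripts do.
- Motif scanning is a local, library-driven replacement for web TFBS
  services; it does not perform de novo discovery or cross-species
  orthology mapping, and its hit counts depend on the curated library
  supplied.
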