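# Methods

## Scope and data model

`triadbalance` analyses homoeolog expression balance in an allohexaploid
genome. Its inputs are (1) a *triad registry* — a table assigning loci (wheat
RefSeq-style Gene_IDs) to genes and, through the identifier's chromosome
letter, to subgenomes; (2) a locus × sample TPM matrix with per-sample
metadata (study, tissue, condition); and (3) optionally FASTA files of
homoeolog coding/protein sequences. Homoeolog discovery (BLAST or otherwise)
is out of scope: the registry is an input. TPM computation from reads is
likewise out of scope: values arrive already normalised.

### Identifier parsing

Gene_IDs are parsed as species prefix (capitalised letters, e.g. `Traes`),
two-letter accession (`CS`), chromosome+subgenome (`1A`–`7D`, or `U` for the
unassigned-chromosome bin), a two-digit assembly-version segment treated as
an opaque string, `G`, a numeric locus identifier kept as a *string* so
leading zeros survive a parse/serialise round trip, and an optional decimal
transcript-isoform suffix. `U` loci parse with subgenome `unknown`; they can
enter analysis only through an explicit override recorded on the registry
entry (`override_flag`, note). Silent guessing is forbidden because such
assignments are genuine analytical assumptions — the packaged wheat registry
carries exactly one, assigning the unplaced Raf2 locus to the D subgenome on
the strength of its ~96% protein identity with the A and B copies.

A gene lacking a copy in some subgenome loads with a warning rather than an
error: incomplete triads are real (deletions, annotation gaps) and the
aggregation remains well defined.

## Aggregation

For a context (a metadata predicate, typically tissue+condition):

1. **Mean TPM per locus** over all passing samples, pooled with equal
   per-sample weight across studies. A study-stratified mode (per-study means
   averaged) is available behind `stratify_by_study=True`; pooled is the
   default because it is the most literal reading of "mean of the samples".
2. **Subgenome totals** `T_s`: sum of the gene's loci means per effective
   subgenome, so multi-copy families (e.g. RbcS with 9/8/8 copies) aggregate
   to one value per subgenome, and override-assigned loci count toward their
   assigned subgenome.
3. **Fractions** `f_s = T_s / (T_A + T_B + T_D)` and **log2 total**
   `log2(T_A + T_B + T_D)`.

Numerical/edge choices:

- A missing (locus, sample) cell is an **error** by default; `fill_missing=
  True` opts into zero-fill. Silent zero-fill hides registry/expression
  mismatches, which in practice are ID typos.
- Zero-total (gene, context) pairs are excluded and *reported* (the fractions
  are undefined at 0); no pseudocount is added to the log2 total, which a
  zero total therefore never reaches.
- Result TSVs are written at 6 decimals; on re-read the fractions are
  renormalised to sum exactly to 1 so downstream simplex checks (tolerance
  1e-6) are unaffected by file rounding.

## Balance classification

Fraction triples live on the 2-simplex. Seven archetype centroids are used:
balanced (1/3,1/3,1/3); X-dominant (1 at X); X-suppressed (0 at X, 1/2 at
each other). Classification is nearest centroid by Euclidean distance in the
raw 3-D fraction space — equivalent up to a constant factor to distance in
ternary-plot coordinates. Ties are broken by a fixed centroid order
(balanced; dominants A,B,D; suppresseds A,B,D), making calls deterministic.

Because the category regions are defined purely by this geometry and no
published numeric boundary for "balanced" exists, every call carries a
**boundary set**: all centroids whose distance exceeds the minimum by at most
ε (default 0.05 in fraction-space distance, configurable). This surfaces
points near several categories — e.g. a 19/16/65 split sits within ε = 0.06
of balanced, A-suppressed, B-suppressed and D-dominant simultaneously —
rather than hiding the ambiguity behind a single label. The boundary set is
monotone in ε by construction.

Ternary coordinates use vertices A=(0,0), B=(1,0), D=(1/2, √3/2):
x = f_B + f_D/2, y = f_D·√3/2 (A bottom-left, B bottom-right, D top). The
optional matplotlib scatter sizes symbols by log2 total expression.

## Condition comparison

For a gene present in two contexts with positive totals, the shift record
holds Δf (summing to 0), the fold change of summed triad expression
(`total_to / total_from`, invariant to common rescaling of both matrices),
its log2, and the two balance categories. **"Changed"** is operationalised as
a category transition at the given ε — the underlying two-group distinction
is qualitative, so the package picks the sharpest reproducible definition and
reports boundary sets alongside for near-threshold cases. Genes present on
only one side are listed separately, never dropped; an empty overlap is an
error.

## Sequence identity

Global alignment is Needleman–Wunsch with affine gaps via
`Bio.Align.PairwiseAligner` (mode `global`). Defaults: BLOSUM62 with gap open
−10 / extend −1 for protein; match +2 / mismatch −3 / gap open −5 / extend −2
for nucleotide; a gap of length L costs open + (L−1)·extend, end gaps
included. Among co-optimal alignments the aligner's first traceback is used —
deterministic for fixed inputs and scoring. Percent identity = 100 ×
identical columns / all columns, with gap columns in the denominator; this is
one of several definitions in use, so identities from other tools are
comparable but not guaranteed bit-identical. Multi-way identity is the mean
over unordered pairwise alignments, not an MSA column statistic. Sequences
are accepted as given — no transit-peptide delimitation is attempted.

The unit and end-to-end tests check the aligner against two independent
oracles: exhaustive enumeration of every global alignment (short pairs) and a
separate memoised three-state affine recursion (all binary-alphabet pairs up
to length 6).

## Synthetic data

The generator emulates the statistical structure the analysis assumes, and
only that structure:

- per (gene, context): expected locus TPM = base_total × true_fraction ÷
  copies-per-subgenome, times a stress multiplier in the designated stress
  context;
- per (locus, sample): a multiplicative log-normal noise factor with mean 1
  and coefficient of variation `noise_cv` (σ² = ln(1+cv²), μ = −σ²/2). TPM is
  positive and heteroscedastic, so a mean-one multiplicative log-normal is
  the simplest standard choice; `noise_cv = 0.2` is used as the default noisy
  condition in tests, a mid-range value for bulk RNA-seq replicate scatter.
- gene copies split their subgenome's share equally — downstream aggregation
  sums copies, so only the subgenome total matters, but the split must be
  defined;
- one seed drives all randomness; identical specs are bit-reproducible.

The homoeolog sequence generator derives three sequences from one random
ancestor, giving each homoeolog *private* substitutions at distinct
positions. Requested pairwise counts n_XY must therefore decompose as
n_X + n_Y with non-negative integers — e.g. {A–B: 4, B–D: 4, A–D: 0} puts 4
private changes on B — and infeasible combinations (odd parity, or mutual
counts violating the triangle decomposition) are rejected rather than
approximated.

What the generator does **not** emulate: study batch effects beyond the
context labels, locus-specific expression heterogeneity within a subgenome,
mapping ambiguity between near-identical homoeologs, read-level sampling
noise, and indel divergence between homoeologs. Passing tests therefore
demonstrate correctness of the estimator pipeline under the stated generative
model, not robustness to those real-data complications.

## Validation experiments and problem sizes

- Fraction formulas checked on 1,000 random triples against direct
  arithmetic (1e-9); classification distances on 1,000 random simplex points
  against a brute-force oracle (1e-12); permutation equivariance of both the
  registry aggregation and the classifier checked exactly.
- Alignment scores checked against exhaustive enumeration (all binary pairs
  to length 4; the enumeration also validates the recursion oracle) and
  against the affine recursion (all binary pairs to length 6).
- Parameter recovery: with noise off, the pipeline recovers true fractions to
  1e-12 and category calls equal the generator truth for a seven-archetype
  gene set. With `noise_cv = 0.2` and 10 samples, the mean recovered fraction
  over 500 balanced triads lies within 0.02 of 1/3 (observed max bias ≈
  3e-4), and per-triad fraction SD is ≈ 0.016.
- `scripts/acceptance.py` re-runs the pipeline on synthetic mirrors whose
  generator truth is set to the published wheat Rca1 values (leaf 22/23/55,
  spike 19/16/65, control 17/53/28 renormalised — the printed control
  percentages sum to 98 from rounding — and a 102 → 3152 TPM heat
  induction) and on sequence mirrors with the published polymorphism
  structure (mature protein 400 aa with 4 B-private changes; 390-aa and
  1125-nt triads with identities 95.9% and 96.8%). Reproducing the published
  numbers from the original public expression data requires downloading the
  per-Gene_ID TPM tables from the wheat expression browser, which this
  package treats as an external input.
- The heat-context fractions (0.12, 0.44, 0.44) used in the stress mirror are
  a qualitative emulation — the published account gives only the direction of
  the shift (B and D near-equal, A low) and the totals — so only the fold
  change is treated as a quantitative mirror value.

## Known limitations

- The "balanced" region is defined by nearest-centroid geometry; any
  threshold-based definition from other pipelines will disagree near
  boundaries. Use the ε boundary sets when decisions hinge on borderline
  calls.
- Percent identity depends on alignment parameters and on the denominator
  convention; figures from GUI aligners may differ in the last digit.
- Contexts pool samples with equal weight by default; strongly unbalanced
  study sizes can dominate a pooled mean (use `stratify_by_study=True` to
  weight studies equally instead).
- The package performs no differential-expression inference; "changed" is a
  descriptive category transition, not a statistical test.
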