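# Methods

`congenicqtl` implements the statistical machinery for dissecting a
quantitative trait locus (QTL) with a branching panel of backcross
congenic mouse strains. The motivating design: an inbred host strain
(B6) carries, in each congenic strain, one heterozygous chromosomal
fragment introgressed from a donor strain (129). Every mouse inherits
zero or one copy of its strain's fragment from the father, so the
genome is two-state at every marker — `A` (B6/B6) or `H` (129/B6) —
and a strain's donor fragment is read directly off a genotyped marker
panel as a run of `H` calls. The trait is the weight of the gonadal
adipose depot, with body weight as a covariate; everything below
applies to any positive continuous trait with the same design.

## Coordinates and interval algebra

All coordinates are 1-based inclusive base pairs. Donor regions are
`IntervalSet`s — canonical sorted disjoint inclusive intervals — and
every mapping step reduces to interval algebra on them: union,
intersection, symmetric difference, inclusive lengths, and the
partition of the covered genome into *atomic bins* cut at every
fragment endpoint. Bins are the resolution limit of breakpoint-based
mapping: no comparison of donor fragments can localize an effect
below the bin level. Operations are implemented by a boundary sweep
(never by enumerating base pairs) and are verified in the test suite
against a brute-force bp-membership oracle on small coordinates.

Donor-region boundaries are reported at the observed marker
positions (inner bounds). The true recombination breakpoint lies
somewhere between the outermost `H` marker and the flanking `A`
marker; inner bounds avoid inventing midpoints and match how
marker-resolved QTL coordinates are conventionally printed.

## Genotype imputation

A missing call (`X`) is filled when the nearest non-missing flanking
markers on the same chromosome carry the same genotype and lie at
most `max_gap_mb` apart (default 26 Mb), the rationale being that a
double recombination inside such a short flanked interval can be
excluded in a backcross pedigree. Disagreeing flanks imply a
recombination of unknown position, so the call stays missing.
Chromosome-terminal missing calls have a single informative flank,
which cannot exclude a distal recombination; they are left missing
unless `fill_terminal=True`. The operation is deterministic,
idempotent, and never alters an observed call.

## Phenotype preparation

Three steps precede all mapping: (1) mice flagged at necropsy (sick,
tumors) are removed; (2) the trait distribution is diagnosed by
moment skewness and a Kolmogorov–Smirnov test against a normal with
estimated parameters, and a natural-log transform is applied when the
raw data are right-skewed (skewness > 0.5) or the KS screen rejects
at 0.05 — with estimated parameters the nominal KS p-value is
anti-conservative (Lilliefors caveat), so it is used as a coarse
flag, not a calibrated test; (3) candidate covariates are screened by
Pearson correlation (|r| > 0.3 and p < 0.05). Defaults pin the
standard choice for this design: body weight is always used as a
covariate, and age — tightly controlled at necropsy — never is; both
overrides can be dropped to let the rule decide.

## Pooled marker scan

All mice form one mapping population. At each marker the prepared
trait is fit by ordinary least squares with terms entering in a fixed
order — body-weight covariate, strain, marker genotype — and each
term is tested by its Type-1 (sequential) sum of squares: the drop in
residual SS when the term enters after those before it, with an
F-ratio against the full model's residual mean square. Testing
genotype last makes its test conservative (adjusted for both strain
and body weight); the order is explicit in the result object.

Strains that do not segregate at a marker cannot separate a strain
effect from the genotype contrast there, so their mice are pooled
into one factor level; they still inform the covariate slope and the
residual variance. Rank-deficient designs are handled by the
generalized inverse, with the affected term's df taken from the
design-rank increment and flagged.

Scan summaries: −log10 p per marker against Bonferroni-style
thresholds −log10(α/N) with N the number of markers scanned (α =
0.05 "significant", α = 0.63 "suggestive" — the conventional
one-false-positive-per-scan level); Cohen's D at each marker, the
signed standardized mean difference (mean_H − mean_A)/pooled SD, so
positive values mean the donor allele raises the trait; and
drop-based support intervals, extending from each local peak above
the significant threshold to the outermost markers within `drop`
(default 2.0) −log10 p units of that peak.

## Common segment method

Under a single-QTL hypothesis, strains whose fragment covers the QTL
show a donor–host difference and the QTL lies in the region shared
by all positive strains and absent from all negative ones. Strains
are classified by one joint GLM over strain × genotype cell means
with a body-weight covariate, followed by per-strain Fisher's LSD:
t = Δ(adjusted means)/√(MSE·(1/n₁+1/n₂)) on the joint residual df at
unadjusted p < 0.05 (no multiplicity correction — the classification
is deliberately per-strain, and the output records this). The narrow
analysis keeps strains with ≥ 12 mice per genotype and restricts
donor mice to full-length fragments (a mouse is full-length when its
realized region equals its strain's modal donor region); the broad
analysis keeps all mice of every strain whose genotype groups have
at least 4 mice. The shared-region test then asks, marker by marker,
whether the marker is inside every positive strain's fragment and
outside every negative strain's. Linked QTLs of opposite sign defeat
this method — a fragment spanning both has no net phenotype — which
is precisely what the sequential method exists to resolve.

## Sequential method

**Ordering.** Strains (plus a synthetic host node with an empty
region) form a complete graph weighted by the bp length of the
symmetric difference of their donor regions; the minimum spanning
tree of this graph makes nested neighbors adjacent and disjoint
fragments distant, so consecutive comparisons differ by small
genomic regions. Kruskal's algorithm with deterministic tie-breaking
(weight, then lexicographic node pair) builds the tree; strains with
identical fragments are merged into one node (their mice pool).
Comparisons run along a breadth-first traversal from the host,
children in ascending edge weight — starting, naturally, with the
host against the strain nearest to it.

**Comparisons.** One joint cell-means GLM (groups = each node's
full-length heterozygous mice, plus all homozygous littermates
pooled as the host group; body-weight covariate) supplies adjusted
means and a shared residual MSE. Each tree edge gets an LSD contrast
and a ternary verdict: the child group is *greater than*, *less
than*, or *equal to* its parent (equal = not significant at α =
0.05; non-significance is treated as equality, a power-limited
convention the output flags rather than models).

**Inference.** Donor endpoints cut the covered genome into atomic
bins; each bin may carry no QTL, a trait-raising (+) donor allele,
or a trait-lowering (−) one. An assignment is *consistent* when
(i) every significant comparison's difference region contains at
least one active bin whose oriented sign (bin sign × which side of
the comparison carries the bin) matches the verdict, and (ii) every
equal verdict's difference region contains either no active bins or
active bins of both oriented signs — allowing two linked opposing
QTLs to cancel, a configuration flagged "masked". The search
enumerates assignments in increasing number of active bins (bins
outside every difference region are provably never needed), stops at
the first size with consistent assignments, ranks those by (number
of QTLs after merging adjacent same-sign bins, total active length),
and returns *all* co-optimal models rather than an arbitrary winner.
If nothing is consistent within `max_qtls` (default 6) active bins,
the conflicting comparisons are reported in the error. The test
suite checks the search against an independent exhaustive
enumeration for panels of up to a dozen bins.

**Refinement.** A QTL localized only to a broad interval can be
pinned by external evidence (e.g., a marginal peak from an earlier
intercross): `refine_qtl` replaces the interval containing an anchor
position with a `flank_mb`-Mb window centred on the anchor
(anchor ± flank/2), clipped to the original interval; intervals
already narrower than `min_width_mb` (default 20 Mb) are left alone.

**Effect display.** `qtl_effect_table` reports adjusted host/donor
means with 95% confidence limits at one marker per QTL, using donor
mice only from strains whose fragment covers that QTL and no other —
carriers of several QTLs would blend effects and can even invert the
apparent sign of an opposing-pair member.

## Candidate-gene filtering

Expression evidence comes as per-gene log2 fold change and p-value
from two independent donor-vs-host experiments. Within each
experiment a gene passes at |log2FC| > 0.58 (1.5-fold) **or**
Benjamini–Hochberg FDR < 0.05 (the permissive or-rule is the
default; an and-mode switch exists), and a gene is *reproducible*
when it passes in both experiments and lies inside the donor region
under study. Variant-effect and human-GWAS-orthologue evidence are
consumed as precomputed boolean flags (computing them requires
external databases and is out of scope); the final step
cross-tabulates all 2³ evidence combinations over genes inside the
inferred QTL intervals.

## Synthetic panel generator

The generator produces panels with exactly the structure the
analyses assume, so every stage is testable without external data.

Genotypes: each strain is one contiguous donor fragment; donor mice
carry it heterozygously, truncated from the distal end with
probability `partial_prob` (default 0.1) at a uniform point (a
single paternal recombination; a both-ends option exists), and `H`/
`A` calls are read off the marker map, with optional random `X`
masking. The default marker map has 148 markers spanning ~3–124.6 Mb
with markers anchored at every preset fragment boundary and QTL
position, the rest on a uniform grid.

Phenotypes: body weight ~ N(31, 3) g; age ~ N(180, 2) days;
log depot = b₀ + b_bw (bw − μ) + Σ_q effect_q·σ_pheno·1[fragment ∋ q] + ε,
ε ~ N(0, σ_resid), with b₀ = log(0.5 g), b_bw = 0.08 per g,
σ_resid = 0.35, and σ_pheno = √(σ_resid² + b_bw²σ_bw²) ≈ 0.42 the
host-population SD of the log trait. Scaling effects by σ_pheno
makes a QTL's configured effect equal the expected Cohen's D of the
log trait at a fully linked marker (verified to converge within 0.05
at n ≥ 2,000). Exponentiating yields right-skewed raw weights in a
realistic 0.2–1.5 g range, which is what trips the preparation
stage's log transform; a toggle generates normal residuals on the
raw scale instead. A 1% necropsy-exclusion rate exercises the
exclusion step.

The default preset plants four QTLs at 43.5, 52.5, 54.26 and
113.9 Mb with effects +1.25, +1.25, −1.25, +1.25 across twelve
strains (n = 30 per genotype per strain). Two choices here were
genuinely open and are worth recording:

* **Effect magnitude.** 1.25 SD per QTL, equal magnitudes, was fixed
  a priori by power analysis: a single 30-vs-30 LSD contrast then
  detects one QTL with ~99% power, the regime a sequential congenic
  comparison is designed for, and the equal-magnitude opposing pair
  (QTL2/QTL3) cancels exactly in any fragment spanning both — the
  masked architecture the method exists to expose. Note the pooled
  scan's marginal Cohen's D at a marker is much smaller than the
  per-QTL effect, because the marker's carrier group mixes strains
  whose fragments carry different QTL combinations.
* **Fragment layout.** With four ordered QTLs a contiguous fragment
  can realize only ten distinct non-empty QTL subsets. The preset
  uses all ten, plus two exact duplicate fragments (which the MST
  builder merges, exercising that path). Pairwise-distinct QTL
  content guarantees that *every* possible strain comparison differs
  in at least one QTL, so no tree edge is a pure null contrast whose
  5% false-positive rate would inject spurious QTLs into the model.

A second preset reproduces a realistic 22-strain panel (group sizes
3–176, 1,293 mice in total, including three strains too small to
test) for exercising the narrow/broad selection rules.

What the generator does **not** emulate: residual background
heterozygosity, strain-specific background effects (a random-
intercept toggle was considered and rejected as untestable here),
genotyping error, maternal/litter effects, age structure beyond a
tight window, and multi-fragment donors. Passing tests on synthetic
panels therefore demonstrate the statistical machinery under the
design's own assumptions, not robustness to these real-data
complications.

## Numerical choices and degenerate inputs

* OLS via `numpy.linalg.lstsq`; term df from design-rank increments,
  so rank-deficient factors are handled without pivoting heuristics.
* p-values are floored at 1e-300 before −log10.
* Factors observed at fewer than two levels are dropped with a
  warning (e.g., the strain factor in a single-strain population).
* Markers monomorphic in the analyzed mice get a missing −log10 p
  rather than zero.
* Zero pooled SD makes Cohen's D undefined (NaN, with a warning).
* LSD contrasts of literally identical groups return p = 1 up to
  floating-point noise in the fitted means.
* Test sizes are kept small deliberately (panels of 720–1,293 mice,
  50-seed recovery sweeps, 150-strain type-I batteries); each was
  chosen so the binomial/Monte-Carlo error of the checked quantity
  is several times smaller than the asserted tolerance.

## Known limitations

* The two-state backcross genotype model is assumed throughout;
  F2-style three-genotype data are out of scope.
* Thresholds are Bonferroni-per-marker, not permutation-based, and
  ignore marker correlation.
* Non-significance is equality in the sequential verdicts; true
  small effects below per-comparison power are absorbed into
  neighboring bins or missed.
* Minimality (fewest QTLs, then shortest active length) is a
  parsimony convention; the data typically admit larger consistent
  models, and all co-minimal models are reported to make residual
  ambiguity visible.
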