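# Methods

## Design model

The experimental unit is a genotype trio — female parent, male parent, F1
hybrid — each measured on `n_replicates` biological replicates (default 3,
the usual minimum for a field trial). Input is a quantified protein matrix
(strictly positive intensities, missing allowed) plus a sample map binding
each column to one genotype role and replicate. Proteins are reduced to the
jointly quantified set by complete-case filtering (`complete_cases`): a
protein enters the analysis only if observed in every sample. Genotype-level
summaries are arithmetic means over observed replicates.

## Differential testing

Per protein and genotype pair we use a two-sided pooled-variance Student
*t*-test. Pooling is deliberate: with ~3 replicates per group, per-group
variance estimates are too unstable for Welch's correction to help.
Abundances are log2-transformed before testing (default `log_transform=True`);
intensity noise is multiplicative, so the transform makes the model
approximately (for simulated data: exactly) normal. Fold change is always
the ratio of raw-scale group means, independent of the testing transform.
Raw p-values are Benjamini–Hochberg adjusted across the tested proteins of a
comparison; the significance call uses adjusted p ≤ alpha by default
(`use_fdr=False` switches to raw p, since both conventions are common).
Degenerate zero-variance cases are resolved by continuity: equal means give
t = 0, p = 1; unequal means with zero pooled variance give t = ±inf, p = 0.
Proteins leaving fewer than two observed replicates in either group are
skipped and logged, never fatal.

"Up" means higher in the first-named (test) genotype; the three standard
comparisons are hybrid-vs-female, hybrid-vs-male, and female-vs-male.

## Inheritance-pattern rules

With U = 1.5, L = 0.67, band b = 0.10, HP/LP/MP the high-/low-/mid-parent
means, evaluated in order:

1. L < F1/MP < U → **additive**
2. F1/R_up ≥ U(1+b) → **over_dominant_up**
3. U ≤ F1/R_up < U(1+b) → **high_parent**
4. F1/R_dn ≤ L(1−b) → **under_dominant**
5. L(1−b) < F1/R_dn ≤ L → **low_parent**
6. otherwise → **partial_nonadditive**

Default cut points: 1.65, 1.5, 0.603, 0.67. The additive interval is open;
the outer bands are closed at their cut points (the non-additive side owns
the boundary). Rules are exhaustive and mutually exclusive for any positive
triple, scale-invariant, and symmetric in the parents (property-tested on
10^5 random triples).

Two reference conventions are provided. `mode="literal"` (default) takes
every band ratio against the high parent, R_up = R_dn = HP. This has an
awkward geometric consequence: whenever HP/MP > L/(L(1−b)) ≈ 1.11 — i.e.
any parental divergence above ~1.25-fold — the low_parent region
{F1/HP ∈ (0.603, 0.67]} ∩ {F1/MP ≤ 0.67} is empty, so "hybrid at the low
parent's level" can never be called. `mode="reconstructed"` references the
down-side bands to the low parent (R_dn = LP), the conventional genetic
reading in which low-parent dominance means F1 ≈ LP. Analyses that care
about down-side dominance classes should use `reconstructed`; `literal`
is retained as the default because it follows the published rule text
as written.

Non-additive proteins that fall in no band get an explicit
`partial_nonadditive` label (direction from the side of the mid-parent gate)
rather than being dropped silently.

Summary percentages group over-dominant = rules 2+4 (up and down
outside-parental classes) and dominant = rules 3+5, and are rounded
half-away-from-zero (as are all percentage outputs; `percentage()`
implements this with decimal arithmetic, since binary floats round
0.5-boundaries erratically).

## Heterosis indices

OPH/MPH/BPH are the relative deviations of the hybrid mean from HP/MP/LP in
percent. They are scale-invariant, parent-symmetric, ordered
OPH ≤ MPH ≤ BPH for positive data, and undefined (a named error) when a
denominator is zero. Group means are arithmetic means over replicates.
Pairwise genotype differences are tested with the same pooled t-test as the
proteomics stage; a multiple-range letter display is intentionally not
implemented.

## Enrichment, Venn, clustering, qPCR

Term over-representation is the one-sided hypergeometric upper tail
P(X ≥ k) for k annotated proteins in a DE set of size n against a background
of size N with K annotated (the Fisher construction used for GO testing),
BH-adjusted across terms. The background defaults to all quantified
proteins. The Venn stage is exact set algebra over the three DEP id sets;
`shared_fraction` reports (pair-exclusive region + triple overlap) over a
chosen set's size. Clustering is UPGMA on Euclidean row distances
(scipy's average linkage), with optional per-row z-scoring (off by default)
and Newick export whose branch lengths are merge-height differences.
qPCR relative expression follows Livak: replicate Ct values are averaged on
the Ct scale per genotype before ΔCt, ΔΔCt and 2^−ΔΔCt; the mid-parent
calibrator is the mean of the two parental ΔCt values. No amplification-
efficiency correction is applied.

## Synthetic data

`simulate_quant` plants, per protein: a base abundance (lognormal across
proteins, median 1000, log-sd 1.0 — roughly two orders of magnitude of
dynamic range); parental divergence by `parent_fold` (default 2.0, a clear
but realistic inter-line difference) with the high side assigned to either
parent at random; and a hybrid level set by the planted pattern —
F1 = MP (additive), 2.0·HP (over-dominant), 1.57·HP (high-parent dominant,
mid-interval of [1.5, 1.65)), 0.636·LP (low-parent dominant, mid-interval
of (0.603, 0.67]), 0.45·LP (under-dominant), or no signal at all (null).
Down-side patterns are referenced to the low parent, matching the
`reconstructed` classification geometry (under the `literal` geometry a
consistent low-parent planting does not exist; see above). Every replicate
observation is the planted level times exp(Normal(0, σ)) with
σ = sqrt(ln(1+cv²)) — planted levels are therefore log-scale **medians**,
and arithmetic means converge to median·exp(σ²/2) (tested). Each protein
draws from its own counter-derived substream of the seed, so increasing
`n_proteins` extends the panel without reshuffling earlier proteins.

Default per-replicate `cv` is 0.10, a typical biological-replicate CV for
DIA-quantified proteins; recovery and calibration tests sweep it explicitly
(0, 0.05, 0.2).

The default pattern mix is {null 0.30, additive 0.14, over_dominant 0.32,
under_dominant 0.14, high_parent 0.07, low_parent 0.03}. Over-dominant
classes dominate the non-additive signal, as in strongly heterotic crosses.
The dominant (band) classes are kept a modest share by design: their
defining intervals are only 10% wide, while the ratio of two 3-replicate
means at cv = 0.05 carries ≈ 4.1% log-noise, so proteins planted
mid-interval are recovered with probability ≈ 0.76–0.80 (normal-tail
arithmetic) no matter how good the classifier is. With this mix the
generator meets its recovery contract — 100% label recovery of non-null
proteins at cv = 0 and ≥ 95% at cv = 0.05 with 3 replicates (expected
≈ 96.7%) — while still exercising every class.

What the generator does **not** emulate: peptide-level roll-up,
missing-not-at-random dropout, batch or run-order effects, and correlated
noise between proteins. Passing recovery tests therefore demonstrates the
correctness of the decision rules and statistics under the stated noise
model, not robustness to those real-data artefacts.

`simulate_trait` uses the same lognormal noise around per-genotype means.

## Problem sizes and numerical choices

Simulation-based checks use 2000 proteins × 3 replicates (recovery,
type-I calibration) and 10^5 random triples for classifier property sweeps;
these sizes give sub-percent Monte-Carlo error on the reported rates while
keeping any run comfortably in seconds. Brute-force cross-checks
(O(n³) UPGMA, exhaustive hypergeometric enumeration, step-up BH) run on
small instances (n ≤ 8 rows, N ≤ 12 backgrounds, ≤ 20 p-values) at 1e-10
agreement. Percentages use decimal half-away-from-zero rounding. Boundary
membership of the classification bands follows the closed/open conventions
listed above; tests pin boundary behaviour at the implementation's own
float cut points, since 1.5 × 1.1 is not exactly representable in binary.

## Known limitations

- No imputation: partially observed proteins are dropped by complete-case
  filtering before analysis.
- The literal band geometry cannot produce low_parent calls at realistic
  parental divergence (kept for fidelity to the published rule wording).
- BH adjustment is not idempotent — re-adjusting an adjusted vector changes
  it — so adjusted p-values must not be fed back through `bh_adjust`.
- The pooled t-test with one constant group yields |t| ≤ 1 for any offset;
  detection power at 3 replicates is limited and no moderated-variance
  (empirical-Bayes) option is provided.
- Enrichment treats terms independently: no ontology DAG propagation or
  term–term correlation handling.
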