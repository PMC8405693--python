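# Methods

This note documents the statistical model behind `lfqstab`, the choices
made where the procedure was genuinely open, what the synthetic-data
generator does and does not emulate, and the pipeline's known
limitations.

## Data model and generator

The generator (`lfqstab.simulate`) draws a proteins × samples log2
intensity matrix as

    y_gs = μ_g + δ_g·1[s ∈ DM] + b_batch(s) + ε_gs,   ε_gs ~ N(0, σ²_g)

with per-protein baselines μ_g ~ N(25, 2²) (log2 LFQ scale), residual
variances σ²_g ~ s₀²·d₀ / χ²(d₀) — a scaled inverse-χ², the same family
the empirical-Bayes moderation fits, which is what makes hyperparameter
recovery testable — and batch offsets b ~ N(0, 0.5²) shared by all
proteins of a batch. A fraction `frac_da` (default 0.1) of proteins
carries a disease effect δ_g = ±`effect_size` (default 1 log2 unit, i.e.
a two-fold change, the magnitude typical of the strongest adipose-tissue
hits); the rest have δ_g = 0.

Missingness is probit left-censoring: an entry is observed with
probability 1 − Φ((c − y_gs)/w). Defaults c = 23.2, w = 1.0 place the
50%-dropout point about 0.9 standard deviations below the mean baseline
and produce ≈ 25% missing entries overall (the censor midpoint was
calibrated empirically across seeds to hit that rate; the dropout slope
of ~1 log2 unit is in the range reported for MS LFQ dropout curves). A
further fraction `frac_unique` (default 0.05) of proteins is forced
fully missing in one group, emulating proteins below the detection limit
in one condition only; these carry δ_g = 0 and are excluded from the
quantitative ground truth by construction, since the pipeline handles
them through the detection-limit heuristic, not the regression.

Default residual-variance hyperparameters are d₀ = 4 and s₀² = 0.1
(typical protein-level sd ≈ 0.32 log2 units ≈ 22% CV, realistic for
good-quality LFQ). Samples default to 10 per group in 2 preparation
batches assigned round-robin within each group so disease and batch are
never confounded (both are predictors downstream, so the design must be
estimable). A single integer seed is expanded into independent
substreams per generator stage.

What the generator does **not** emulate: peptide-level structure and
roll-up, correlated proteins (complexes, shared peptides), sample-level
quality gradients, heteroscedastic batch × protein interactions, and
intensity-dependent variance. Passing tests therefore demonstrate
correctness of the pipeline's logic under its own model assumptions, not
performance on any particular real data set.

## Normalization and routing

Median equalization is performed on the log2 scale by an additive
per-sample shift to the median of per-sample medians; missing entries
are ignored when computing medians (zero-filling would distort them
under censoring) and remain missing. The transform is idempotent and
preserves within-sample differences, hence fold changes.

Routing sends a protein to the quantitative path iff it has ≥ 4 observed
values in *each* group (inclusive). The detection-limit heuristic calls
`unique_DM` when a protein is observed in ≥ nmin DM samples and ≤ nmax
NDM samples (symmetrically for `unique_NDM`), defaults nmin = ⌈0.7·n⌉
and nmax = ⌊0.1·n⌋ — 7 and 1 for groups of 10. The thresholds are
deliberate design choices (exposed as configuration): strict enough to
honor "uniquely expressed" while tolerating one stray identification.
Recovery of planted group-unique proteins is only expected when the
present group is well observed; under heavy global censoring a
low-abundance unique protein can fail the ≥ 0.7 presence rule, which is
intended behaviour, not a defect.

## Differential abundance

Each imputation round completes the matrix group-wise: missing entries
of protein g in group G are drawn independently from
N(mean, sd) of the observed (g, G) values (sd with ddof = 1; routing
guarantees ≥ 4, and imputation requires ≥ 2, observed per group). Per
protein, OLS on intercept + disease indicator + reference-coded batch
dummies (reference = lexicographically first batch; the disease
coefficient is invariant to that choice) yields β̂ (DM − NDM, log2),
s², and d = n − rank(X) residual df. Rank deficiency (batch confounded
with disease) is rejected before fitting.

The empirical-Bayes prior (d₀, s₀²) is estimated per round by moment
matching on log s²: with e = log s² − ψ(d/2) + log(d/2), solve
ψ′(d₀/2) = Var(e) − ψ′(d/2) by Newton inversion of the trigamma
function, then s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)). When the
dispersion of log-variances does not exceed ψ′(d/2) there is no positive
solution: d₀ = ∞ and s₀² is the mean variance (complete pooling).
Exact zeros are excluded from estimation and moderated normally
afterwards. The prior is re-estimated every round because each completed
matrix is a different data set.

Moderation: s̃² = (d₀s₀² + d·s²)/(d₀ + d); t = β̂/(s̃·√c_dd) referred to
Student t with d₀ + d df (d when d₀ = ∞; d₀ = 0 reproduces classical
OLS exactly, which is the oracle test). q-values default to
Benjamini–Hochberg (deterministic, no tuning); Storey q-values with the
λ = 0.5 π₀ estimator are available by flag and equal π₀-scaled BH.

Aggregation over M rounds (default 50): n_pass counts rounds with
q < 0.1; a protein is called iff n_pass ≥ ⌈0.6·M⌉ (30 of 50). The
reported log2 fold change, q and t are medians across rounds — the
summary statistic is not dictated by the procedure itself; medians were
chosen for robustness to occasional extreme imputations. Direction
follows the fold change of called proteins. Round r draws from an
independent substream of the master seed, so rounds are exchangeable and
the full run is bit-reproducible.

### Known limitation: anticonservativeness under missingness

Treating imputed entries as observed data understates uncertainty. For a
protein with n_obs of n entries per group, the true sampling variance of
β̂ is ≈ σ²(1/n_obs,DM + 1/n_obs,NDM) while the model uses σ²·(2/n),
inflating |t| by roughly √(n/n_obs); censoring additionally deflates the
observed sd. With thousands of tests, BH then admits a stable cluster of
null proteins whose observed-data noise happens to be extreme — and
because that noise is fixed by the observed entries, the pass-rate
filter cannot remove it (repeating the imputation only averages over the
imputation draws, not over the data). Quantitatively, under this
package's own generator at 25% censor-driven missingness the pipeline
produces a few false calls per 2000-protein null replicate, and the
realized false-discovery proportion under planted effects runs slightly
above the nominal 10% (≈ 0.15–0.20), while with fully observed data the
same pipeline is exactly calibrated (BH's global-null rejection
probability). Users should read the pass rate as a stability diagnostic,
not as a calibrated error rate, and treat borderline calls with heavy
missingness skeptically. Rubin-style multiple-imputation pooling would
restore calibration but is a different procedure from the one this
package implements.

## Set enrichment and clustering

The category score is the mean of member t statistics (median t across
imputation rounds). The null is protein-label sampling: B random
equally-sized subsets of the scored universe (sample permutation is
impossible from a per-protein statistic interface). Implementation
detail: one random ordering per draw provides nested uniform subsets of
every size via prefix means, so all category sizes share the same B
draws. Directional p-values use the add-one convention
p_up = (1 + #{null ≥ obs})/(B + 1) — p is never zero and a category
equal to the whole universe gets p = 1 in both tails. B defaults to
10,000. BH is applied within each direction; significance at
min(q_up, q_down) < 0.10.

Redundancy clustering uses overlap-coefficient distance
1 − |A∩B|/min(|A|,|B|) rather than Jaccard so that nested parent/child
GO terms (distance 0) collapse. Average-linkage clustering is cut
statically at 0.7, then clusters smaller than `min_nodes` (default 3)
are iteratively merged into their nearest cluster while the average
between-cluster distance stays ≤ 0.8 — a deterministic approximation of
adaptive tree cutting that reproduces the needed behaviour (redundancy
collapse plus the minimum-size rule) with a testable definition.
Tie-breaks are lexical throughout, so clustering is invariant to input
order. Each cluster reports its lowest-p member (ties: larger |mean t|,
then lexical id); clusters with ≥ 3 members are flagged for inclusion.

## Concordance

DEG thresholds are p ≤ 0.05 and |logFC| ≥ 0.5, both inclusive ("at
least" semantics; the p boundary is inclusive for symmetry). Protein
accessions map to gene symbols through a user-supplied two-column table —
no live database lookups, keeping runs offline and reproducible;
unmapped accessions are reported in a side list, never silently dropped.
Category lists from the two layers are intersected as given: the package
does not attempt to harmonize how each layer defined significance.

## Problem sizes and numerical choices

Simulation-based checks use 2000-protein studies (20 null replicates at
M = 20; 10 planted-effect replicates at M = 50), 1000-protein studies
for category and unique-expression recovery, and a 500-protein full
pipeline for byte-reproducibility — sizes chosen so the whole suite and
the acceptance script each run in minutes on a single core while keeping
Monte-Carlo error well inside the stated tolerances. Trigamma inversion
runs Newton to 1e-10 relative steps; degenerate cases (zero variances,
constant statistics, single categories, empty samples) are handled
explicitly and tested. All randomness flows from a single integer seed
through `numpy` SeedSequence substreams; no global RNG state is used.
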