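# Methods

This note documents the models, parameter choices and numerical decisions
behind `offsig`, and what its synthetic-data tests do and do not establish
about real data.

## Screen scoring

Each 384-well plate carries 24 DMSO vehicle wells, 8 etoposide
positive-control wells and 176 compounds in duplicate. Normalization is
strictly per plate (and per cell line): POC = 100·L/L̄_vehicle, and
ΔPOC = 100·(L̄_vehicle − L̄_compound)/L̄_vehicle on duplicate-averaged
luminescence, so POC + ΔPOC = 100 identically — this complementarity is an
invariant, not an approximation. The per-compound test is a one-way ANOVA
on the two-level group factor fitted as a linear model against the plate's
24 vehicle wells; for two groups this F-test equals the pooled-variance
two-sided t-test (F = t²), and the vectorized screen path exploits that
identity. Multiplicity is handled with Benjamini–Hochberg step-up.

The hit gate intersects adj. p ≤ α (default 0.05) with a ΔPOC percentile
limit. The percentile's reference population is a genuine design choice:
the default takes the 95th percentile (linear-interpolation, type-7
convention) over *all* screened compounds and then intersects with
significance; `percentile_over="significant"` restricts the reference to
the significant subset first. With ~5% true actives both give nearly the
same gate. Cross-cell-line reduction of ΔPOC is the mean by default
(`reduce="max"` available); the positive-control wells feed only a
Z′-separation QC report, never normalization.

Spatial diagnostics run Kruskal–Wallis across rows and across columns of
sample-well POC plus an edge-vs-interior median difference, BH-adjusted
across plates; constant or single-row plates are marked not-computable and
never flagged. B-score/median-polish correction is deliberately out of
scope — the diagnostics exist to justify *not* correcting.

## Chemical similarity

Fingerprints default to 1024-bit Morgan (radius 2) bits when RDKit is
present. The fallback — FNV-1a hashing of all substrings of length 1–7 of
the SMILES text into the bit space — exists so the module is fully
functional and testable without a cheminformatics toolkit; its provenance
is recorded per fingerprint (`source`), and real analyses can require
toolkit fingerprints. Tanimoto similarity of two empty fingerprints is 1
by default (configurable to 0).

The significance layer fits Beta(α, β) by the method of moments to
observed Tanimoto scores binned on the pair's minimum set-bit count
(bin width 32 bits; ≥ 10 scores per bin; scores clamped into
(10⁻⁶, 1−10⁻⁶) to keep moments finite). Bins with degenerate variance are
marked unfit and fall back to the global fit with a warning. Clustering
treats the similarity matrix's *rows* as profile vectors, takes Euclidean
distances and applies average-linkage agglomeration; merge heights are
monotone non-decreasing, and the implementation is cross-checked in the
test suite against an independent O(n³) agglomerative oracle.

## Signatures and enrichment scores

Marker selection follows a two-step recipe: a pooled-variance Student
t-test (P ≤ 0.05, two-sided) filters modulated genes, then the
signal-to-noise ratio (μ_A − μ_B)/(σ_A + σ_B), with each group σ floored
at max(0.2·|μ|, 0.2), ranks them; the top k = 100 positive and bottom 100
negative SNR genes form the up/down lists, ties broken by gene id. The
filter-then-rank order is the default (`apply_filter=False` disables the
gate); Welch's correction is intentionally not the default because the
classical Student form is the documented test. Genes with zero pooled
variance get a missing p and are excluded with a flag.

ssGSEA ranks a sample's genes by value descending and accumulates the
difference between the |value|^0.25-weighted in-set ECDF and the unweighted
out-of-set ECDF over all rank positions; at weight 0 the score is a pure
rank statistic (invariant to monotone transforms — a property test). The
optional normalization divides by the number of genes for cross-sample
comparability.

The per-cell score is a Mann–Whitney U statistic on within-cell expression
ranks (1-based, descending, average ties): signature ranks are clipped at
r_max + 1 = 1501, U′ = Σ ranks − n(n+1)/2, score = max(0, 1 − U′/(n·r_max)),
and cells at score ≥ 0.2 are flagged as the leukemic population. The
contract is this formula; exact numerical parity with any particular
single-cell scoring package is not claimed. Note the floor case: when every
signature gene exceeds r_max the score is (n−1)/(2·r_max) ≈ 3·10⁻⁴, i.e.
effectively but not identically zero.

## Connectivity-map class enrichment

Given an externally ranked perturbagen list (rank 1 = strongest signature
match), the statistic is the count/fraction of a compound class inside the
top K = 250. The bootstrap null resamples same-size molecule sets uniformly
without replacement from the ranked library — the simplest null consistent
with resampling "sets of molecules" — with p = (1 + #{null ≥ obs})/(B + 1),
so p ≥ 1/(B+1) and the same seed reproduces the result bitwise. Sampling
is vectorized (random-key `argpartition`, chunked over replicates) so it
stays independent of the closed-form route. That closed form — the
hypergeometric upper tail P(X ≥ obs) — is always reported alongside; the
two agree within Monte-Carlo error by construction, and the test suite
checks both the agreement (3 MC standard errors at B = 50,000) and null
calibration (KS uniformity at 1% over 200 seeded null rankings; the
calibration design uses a wide count distribution, N = 2000, m = 500,
K = 1000, because the KS statistic of a discrete test's p-values is floored
by its largest atom). Tau-score computation and querying of external
connectivity services are out of scope; their exports are this module's
input.

## Dose–response

The 4PL model y = bottom + (top − bottom)/(1 + (x/IC50)^hill) is fitted on
log10 dose by bounded least squares with bottom ∈ [−10, 50],
top ∈ [50, 120], hill ∈ [0.1, 10] and five log-spaced IC50 starts spanning
the tested range; the best solution wins and the `converged` flag reports
the optimizer's own status. Bounds prevent pathological fits on partial
curves; flat responses raise rather than returning a fake IC50. AUC is the
trapezoidal integral of viability vs log10 dose with viability clipped at 0
(no negative-area credit), reported raw (percent·log10 μM) and normalized
by 100 × the log-dose range so a fully viable curve scores 1 — both scales
are emitted because published AUC figures do not state which is used.
Group sensitivity uses the two-sided Mann–Whitney U, exact (no ties, both
n ≤ 8) or normal-approximated with tie correction; the switch point is
stated because implementations differ.

## RIME interactor calling

The spectral route calls a protein when SPEC ≥ 5 in *every* bait replicate
while the IgG control fails the criterion. "Fails" is ambiguous in the
underlying protocol, so the default is strict — SPEC < threshold in every
IgG replicate (`igg_rule="all_below"`) — with a mean-ratio alternative
(bait mean ≥ 2× IgG mean). The IgG threshold is decoupled from `min_spec`
(defaulting to it) so that raising `min_spec` can only shrink the hit list.
A `mode="mean"` variant applies the threshold to the replicate mean, since
published hit lists may have used either reading.

The LFQ route log2-transforms intensities, imputes missing values per
sample column from Normal(μ − 1.8σ, (0.3σ)²) — the de-facto defaults of
this workflow, motivated by intensity-dependent (MNAR) dropout — then runs
a pooled two-sample t per protein. The permutation FDR relabels columns
(all distinct relabelings when ≤ B, else B random ones, identity excluded
from the null catalogue), estimates q as the average null exceedance count
over the observed count at each |t|, and monotonizes by suffix minimum.
The significance gate follows the stated rule exactly: p < 0.05, log2 fold
change ≥ 2 toward the bait, ≥ 2 peptides; q is reported for inspection but
is not part of the gate, and no s0 moderation is applied. Intersection
across samples is an exact set operation keyed on gene symbol, ordered by
mean SPEC; gene-set overlap reports hypergeometric enrichment against a
caller-stated background universe (the correct universe for a given
annotation release is the caller's responsibility).

## Synthetic-data generators and what the tests show

Every generator is a pure function of its arguments including the seed, and
truth tables are emitted separately from the data files — no truth column
ever appears in a generated input.

* **Screen**: lognormal plate baselines (CV 15%) mimic luminescence
  positivity; multiplicative well noise at CV 5%; actives scale the mean by
  (1 − ΔPOC/100) with planted ΔPOC 95 on 5% of 5292 compounds — the scale
  and hit-rate regime of the screen the pipeline targets. Optional additive
  edge bias feeds the spatial diagnostics.
* **Expression**: Normal(0, 1) background with 100 up and 100 down genes
  shifted by 2σ, 16 samples per group. The group size was set so the
  two-step selection has essentially complete per-gene power at the planted
  2σ effect; at small n (3–4 per group) the Student filter's power (~0.6)
  caps recovery well below what the selection itself could achieve.
* **Ranking**: class ranks drawn without replacement with weight
  exp(−s·rank/N); s = 0 is the exact null, and s ≈ 9.4 places ~56% of a
  32-member class in the top 250 of 2836 — the concentration regime of an
  enriched inhibitor class.
* **Proteomics**: Poisson spectral counts (bait λ = 12 for the 50 planted
  interactors, background λ = 1), log2 intensities Normal(base, 0.4) with
  base ~ Normal(25, 1) and a +3 bait shift for interactors, and logistic
  MNAR dropout (steepness 2, overall rate ≈ 0.2 near the intensity median).
  Three flagged decoy/contaminant rows exercise table QC. An optional
  `interactor_seed` fixes the planted complex across samples so
  intersection behaves like biological replicates of one pulldown.
* **Dose–response**: exact 4PL means over a 0.03–10 μM half-log series
  plus i.i.d. normal noise.

Passing tests on these generators demonstrate that the *statistics* behave
as designed — exact complementarity, calibrated nulls, stated error
control, recovery at the planted effect sizes. They do not demonstrate
robustness to what real data add: batch effects and plate drift beyond a
lognormal baseline, correlated genes, heavy-tailed intensity noise,
peptide-level quantification artifacts, or compound annotation errors.
Real-data replication should treat the package's outputs as it would any
screen analysis: check plate QC, inspect the ΔPOC distribution, and
confirm interactors orthogonally.

## Problem sizes and determinism

The shipped test suite and the acceptance script run at the study scale
where that is cheap (the 5292-compound screen, the 2836-item ranking) and
at desk scale elsewhere (1000-protein tables, 2000-gene matrices,
100-curve dose–response batches; 20 seeds for error-rate estimates, 200
for null calibration). All stochastic steps take explicit seeds;
re-running any stage with the same configuration reproduces outputs
byte-for-byte, which the pipeline's run report verifies by digest.
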