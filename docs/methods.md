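# Methods

This note documents the models, defaults and design choices behind
`protmr`, and what the synthetic experiments do and do not establish.

## Summary statistics and harmonization

All analyses run on GWAS/pQTL summary statistics (per-SNP beta, SE, p,
effect-allele frequency, sample size) on GRCh37 coordinates, 1-based
inclusive. Exposure and outcome studies are aligned to a common effect
allele: exact matches pass through, swapped alleles flip the outcome beta
and reflect its EAF, and complementary (strand-flipped) alleles are
complemented first. Palindromic SNPs (A/T, C/G) cannot be oriented from
allele labels, so after textual alignment the orientation must be
confirmed by frequency: both EAFs outside [limit, 1−limit] (default limit
0.42) and on the same side of 0.5, else the SNP is dropped as ambiguous;
palindromes with a missing EAF are always dropped. This is a deliberately
conservative, fully audited policy — every drop carries a reason code.

Instrument selection uses p < 5×10⁻⁸, a cis window of ±1 Mb around the
gene's transcription start (caller-configurable; the colocalization region
uses ±500 kb), MHC exclusion (chr6:26–34 Mb) and greedy LD clumping at
r² < 0.001: SNPs are ranked by ascending p (ties by position, then id, for
determinism), the best is kept and everything at r² ≥ the limit with a
kept SNP is discarded. LD comes from a caller-supplied r² matrix — the
package never fetches reference panels, and SNPs absent from the matrix
are dropped with a log entry by default (a hard-error mode exists).

## MR estimators

Wald ratio for single instruments (first-order SE se_out/|β_exp|, accurate
when the instrument F-statistic is large; the Monte-Carlo check in the
tests conditions on |β_exp|/se_exp > 10). IVW is the primary multi-
instrument estimator, fixed-effect with first-order weights
w_j = β²_exp,j/se²_out,j for the point estimate; its SE uses the
delta-method ratio variance v_j = (se²_out,j + β̂²·se²_exp,j)/β²_exp,j,
se² = Σw²_j v_j/(Σw_j)², which collapses to the familiar (Σw_j)^(−1/2)
when exposure SEs are negligible but accounts for exposure-side
uncertainty when it is a non-trivial fraction of the ratio variance. At
the synthetic study conditions (|θ| = log 0.35, instrument z-scores
15–45) the first-order SE is deflated by ~6% and covers at ~0.93; the
delta form restores coverage to ~0.945, with the remaining half-percent
the usual weak-instrument plug-in residual that vanishes as instrument
strength grows. A multiplicative random-effects inflation
max(1, √(Q/df)) is available behind a flag. Cochran's Q is reported so heterogeneity is visible either
way. MR-Egger orients instruments to β_exp ≥ 0 and fits a weighted
regression with free intercept; slope and intercept use t inference with
k−2 df, which is exact under the weighted-normal model. Weighted median
interpolates the ratio estimates at cumulative weight 0.5; the mode
estimators take the argmax of a Gaussian-kernel density over the ratios
(IVW weights vs equal weights) with a modified-Silverman bandwidth
0.9·min(sd, IQR/1.349)·k^(−1/5) times a user factor. Median and mode SEs
come from a seeded parametric bootstrap (default 1000 draws) that redraws
per-SNP betas from their sampling distributions. All p-values are
two-sided normal except Egger's t. Confidence intervals are Wald-normal;
OR = exp(β) with CI exp(β ± 1.96·se).

The screen's multiple-testing family is the number of proteins actually
tested (Wald and IVW results share one family), with threshold α/m.

## Directionality

Steiger filtering compares per-instrument variance explained,
r² = t²/(t²+n−2), computed the same way for quantitative and binary traits
(binary on the observed scale); an allele-frequency form
2·eaf·(1−eaf)·β² is available for standardized quantitative traits. The
Steiger p-value is a two-sided z-test on the difference of Fisher-
transformed correlations. Reverse MR re-runs selection + harmonization +
IVW/Wald with the disease GWAS as exposure; a protein is excluded as
reverse-causal when that estimate has p < 0.05, or when Steiger filtering
removes every instrument. Zero usable reverse instruments yields an
explicit "untestable" status, never a silent pass.

## Colocalization

Wakefield's closed-form log ABF, lABF = ½[log(1−r) + r·z²] with
r = W/(V+W), is computed per SNP and trait; hypothesis weights are
H0: 0, H1: log p1 + S1, H2: log p2 + S2, H3: log p1 + log p2 +
logdiff(S1+S2, S12), H4: log p12 + S12, where S1, S2, S12 are log-sum-exp
aggregates of lABF1, lABF2 and their sum over the shared SNPs. All
arithmetic stays in log space, so |z| beyond 30 cannot underflow; the
posteriors sum to 1 within 1e-10 by construction. Priors default to
p1 = p2 = 1e-4, p12 = 1e-5, with effect-size prior SD 0.15 for the
quantitative protein trait and 0.2 for the binary outcome — the documented
defaults of the standard single-causal-variant model, whose assumptions
(at most one causal variant per trait in the region) are inherited.
Support labels: strong at PPH4 ≥ 0.75; moderate at PPH4 ≥ 0.60 by default,
with a 0.50 preset exposed (`moderate_low`) because both conventions
appear in practice; the tier classifier uses the strict PPH4 > 0.75.

## Mediation

Two-step MR: protein → factor effects on the protein's instruments, factor
→ outcome on the factor's instruments; the total effect is taken from the
primary protein → outcome screen rather than re-estimated. The indirect
effect is the product β₁β₂ with first-order delta SE
√(β₁²se₂² + β₂²se₁²) — exact, deterministic arithmetic. Mediators must
have p < 0.05 in both steps and an indirect effect with the sign of the
total; BH-adjusted step-1 p-values are reported alongside the nominal
ones so either gating convention can be applied. Proportions mediated are
percentages with sign retained; values outside [0, 100]% are flagged
"inconsistent mediation", never clamped.

## Differential expression

Per-gene pooled two-group variances s²_g (d df) are shrunk toward a prior:
s̃² = (d₀s₀² + d·s²)/(d₀+d), with (d₀, s₀²) fitted by moment-matching the
mean and variance of log s² under the scaled-F model (trigamma inversion
by Newton iteration; a non-positive excess variance yields d₀ = ∞,
i.e. complete shrinkage). The moderated t uses d₀+d df. With d₀ = 0 the
statistic reduces exactly to the ordinary pooled t — the limit case is a
regression test — and the implementation is cross-checked against the
reference empirical-Bayes implementation in R on a fixture. Significance
combines |log2FC| > 1 with BH-adjusted p < 0.05. Inputs are assumed
already log2-normalized; count-model dispersion estimation and batch
correction are out of scope. Cross-dataset concordance requires
significance in both datasets with matching fold-change sign;
single-dataset evidence is retained under its own flag, and the evidence
tier's expression flag is satisfied by significance in either dataset
(a stricter both-datasets flag is also emitted).

## Evidence tiers

Only MR-significant proteins are tiered (anything else is a hard error).
Four boolean supports are counted: PPH4 strictly above 0.75, differential
expression, a PPI edge (confidence ≥ 0.40, inclusive) directly linking the
protein to a known drug target, and a caller-provided druggability flag.
4/3/2/≤1 supports map to tiers 1/2/3/4; the classifier is monotone by
construction. MR direction vs expression direction (protective proteins
down-regulated in tumors) is reported as a separate consistency flag.

## Synthetic data: what it emulates

Generators produce summary statistics directly — no individual-level
sampling. Regional z-scores follow MVN(R·z_causal, R) on an AR(1) grid
R_ij = ρ^|i−j| (default ρ = 0.9, 60–100 SNPs); betas and SEs are
back-derived with se = 1/√(n_eff·2·maf(1−maf)), n_eff = n·φ(1−φ) for a
binary trait with case fraction φ, so z = β/se and the stated p-values
hold exactly. Cohort sizes default to the emulated sources: 54,219 for the
pQTL study and 7,426 cases / 55,627 controls for the outcome GWAS. The
full-study generator plants five causal proteins (log-OR between
log 0.35 and log 2, alternating protective/risk) with sentinel cis-pQTLs
at |z| ≈ 35 — within the range of real sentinel cis-pQTLs and chosen so
the weakest planted effect is detected with >99% power at these cohort
sizes — plus disease-specific loci for reverse MR, a smoking-like
mediation chain planted at 69.46% of one protein's total effect,
expression shifts of |log2FC| = 2 matching each MR direction (one protein
deliberately dysregulated in only one dataset), PPI edges straddling the
0.40 cutoff and mixed druggability flags, so every downstream branch is
exercised. Directional pleiotropy in the screen generator is defined in
the β_exp > 0 orientation (a constant direct effect on sign-mixed
instruments would cancel once estimators orient them).

One global seed expands into per-component child seeds via
`SeedSequence(seed, spawn_key=...)`; every generator and the whole
pipeline are bit-reproducible given (parameters, seed), and pipeline data
outputs are byte-identical across re-runs (the manifest additionally
records wall-clock times).

What passing these tests does *not* show: real LD is not AR(1), real
pleiotropy is not a constant, binary-trait effects here live on the
observed/log-odds scale without liability-scale corrections, and the
expression generator draws gene variances from exactly the inverse-
chi-square family the moderation model assumes. Calibration and recovery
on this synthetic world validate the estimators and plumbing, not the
biology of any particular dataset.

## Numerical and testing conventions

Monte-Carlo rate assertions in the test suite compare an empirical rate
against its theoretical value plus a one-sided 99% binomial margin
2.33·√(p(1−p)/n), fixed in advance — a correct implementation sits inside
the margin, which only absorbs finite-replicate noise. Replicate counts
(200 null screens of 200 proteins, 500 recovery reps, 200 colocalization
regions per scenario, 100 expression simulations) keep the default suite
and the acceptance script at desk scale on one CPU. Degenerate inputs are
defined, not special-cased away: identical ratios give Q = 0 and p = 1,
zero kernel bandwidth returns the common ratio with SE 0, a single-SNP
region sets the H3 weight to −∞ with a note, p-values are clamped to
(tiny, 1], and a zero total effect flags the proportion mediated as
undefined.
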