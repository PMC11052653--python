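# Methods

This note documents the statistical models behind `cosmix`, the defaults
and why they were chosen, what the synthetic data generator does and does
not emulate, and the designs of the validation experiments that
`tests/test_acceptance.py` and `scripts/acceptance.py` run.

## Reference panels and harmonization

A panel stores per-population dosage matrices (counts of the panel `a1`
allele, values 0/1/2) over one shared variant list. Only biallelic SNVs
are kept; VCF records with any missing genotype are dropped panel-wide so
that covariance estimates always come from complete columns. Coordinates
are 1-based inclusive throughout.

Study tables are matched to the panel by (chr, bp) with allele
verification rather than by rsid, because rsid assignments drift across
dbSNP builds while positions within one build are authoritative. A study
row whose alleles are swapped relative to the panel is flipped
(`z := -z`, `af1 := 1 - af1`). Palindromic SNPs (A/T, C/G) are dropped by
default: their strand cannot be verified from allele labels, and an
undetected strand error at such a site silently corrupts every downstream
correlation-based computation. An optional `keep` policy retains them,
orienting allele frequencies toward the panel's mixture frequency (for
Z-tables it trusts the labels). No genome-build liftover is attempted;
build consistency is the caller's responsibility.

## Mixture LD

For mixing proportions $\pi$ the pooled covariance uses the law of total
covariance: within-population covariances plus the between-population
mean-divergence term $\sum_k \pi_k (\mu_k-\bar\mu)(\mu_k-\bar\mu)^\top$.
The mixture is formed on the covariance scale and standardized afterwards.
This is the only formulation that reproduces the correlation of an
actually pooled cohort: allele-frequency divergence between ancestries
induces real correlation between physically unlinked variants in an
admixed sample, and a weighted sum of per-population correlation matrices
(available as `method="correlation"` for comparison) misses it — on the
packaged examples by as much as 0.6 in single entries.

Sample covariances use the $1/(n_k-1)$ denominator for unbiasedness; at
reference-panel sizes the difference from $1/n_k$ is negligible, but the
choice is fixed for determinism. Variants that are monomorphic under the
requested mixture have no defined correlation and are dropped with a
warning (and listed on the result) rather than zero-filled, preserving
the unit-diagonal invariant.

## Ancestry estimation

**From allele frequencies (afmix).** The cohort frequency of variant $j$
in an admixed cohort is $\sum_k \pi_k f_{kj}$ in expectation, so $\pi$ is
the constrained-least-squares solution over the probability simplex.
SNPs are filtered to panel-wide MAF ≥ 0.01 (low-MAF rows carry almost no
contrast and amplify noise) and thinned to every 10th variant so that
residuals are approximately independent despite LD; both are options.
The solver augments the design with a sum-to-one row scaled by
$10^4 \times$ the mean column norm and runs non-negative least squares,
then renormalizes — deterministic, exact on noiseless mixtures, and free
of iterative-optimizer tuning.

**From Z-scores (zmix).** Under a predominantly null or highly polygenic
GWAS, nearby Z-scores are approximately $N(0, R(\pi))$ with $R(\pi)$ the
cohort's mixture LD, so the Z-scores themselves identify $\pi$ whenever
the candidate populations differ in LD and/or allele frequencies. The
estimator maximizes a windowed Gaussian composite likelihood: measured
SNPs are grouped into runs of neighbours within `window_bp` (default
100 kb), chunked to at most `max_snps` (default 30) per window, and

$$\hat\pi = \arg\min_{\pi \in \Delta} \tfrac12 \sum_w
\left[\log\det \tilde R_w(\pi) + z_w^\top \tilde R_w(\pi)^{-1} z_w\right],$$

where $\tilde R_w = (R_w + 0.05 I)/1.05$ keeps each window matrix
invertible. We evaluated the more obvious moment-matching alternative —
least squares of pairwise products $z_i z_j$ against $r_{ij}(\pi)$ — and
found it inconsistent at realistic scale: the noise of Z-score products
is strongly correlated within LD blocks, and with a few hundred
independent blocks it swamps the between-population LD contrast (errors
of 0.1–0.3 on a 70/30 mixture at 2000 SNPs, versus ~0.01–0.07 for the
composite likelihood). For genome-scale inputs at most `max_windows`
(default 500) windows are used, subsampled with a fixed seed (default 42,
a CLI flag). Optimization is SLSQP on the simplex from the barycentre and
vertex-leaning starts; if all single-population candidates give the same
objective within $10^{-4}$ (e.g. duplicated panels), the result carries a
non-identifiability warning.

The estimand in both cases is the composition of the cohort that was
actually sampled. In simulation the cohort's realized ancestry fractions
fluctuate around the target mixture by $\sqrt{\pi_k(1-\pi_k)/n}$ (≈ 0.011
per component at n = 2000), and the estimators track the realized
fractions, not the target: recovery experiments therefore compare against
the realized composition returned by the generator.

## Z-score imputation

`conditional_impute` implements the conditional mean of a multivariate
normal with a ridge: $A = (\Sigma_{oo} + \lambda I)^{-1}$,
$\hat z_u = \Sigma_{uo} A z_o$, $\mathrm{info}_u$ the diagonal of
$\Sigma_{uo} A \Sigma_{ou}$. One Cholesky factorization per window is
shared by all unmeasured variants ($O(m_o^3 + m_u m_o^2)$); the explicit
inverse is never formed. The condition number is estimated from the
Cholesky diagonal and solves with condition $> 10^{12}$ are refused with
advice to raise $\lambda$.

Defaults: $\lambda = 0.1$ on the correlation scale, which keeps solves
safe for panels down to a few hundred individuals; flank 250 kb around
1-Mb cores, covering typical LD range so core-variant results are
insensitive to the tiling (exactly so when LD is block-diagonal within
flanks); imputation universe = panel variants with pooled-mixture MAF ≥
0.001; predictions with info < 0.3 are flagged rather than reported.

Reported p-values use the standardized score
$z_{std} = \hat z/\sqrt{\mathrm{info}}$, whose null variance is exactly 1
at $\lambda = 0$. Any $\lambda > 0$ makes $z_{std}$ conservative
(variance $\mathrm{diag}(\Sigma_{uo}(A - \lambda A^2)\Sigma_{ou})/
\mathrm{info} < 1$); at $\lambda = 0.1$ the null rejection rate at
$\alpha = 0.05$ is ≈ 0.039 in our designs versus ≈ 0.048–0.052 at
$\lambda = 0$. The calibration experiment therefore runs at
$\lambda = 0$, where the nominal level is a mathematical identity and the
test checks the implementation rather than the ridge's (known,
deliberate) conservatism; the default remains 0.1 for numerical safety
on real panels.

## Gene-level tests

Annotations map SNPs (by rsid) to genes, free-form functional categories,
and weights. Per category, $U_c = w_c^\top z$ has null variance
$w_c^\top R w_c$; standardized scores $S_c$ are combined through the
category-score correlation $Q$ with a pseudoinverse
(eigenvalue cutoff $10^{-8}$), giving $T = S^\top Q^+ S$ with
$df = \mathrm{rank}(Q)$ — duplicated or collinear categories collapse
df instead of inflating the statistic, and $T$ is invariant to rescaling
any category's weights. Annotated SNPs missing from the study are imputed
from measured variants within 250 kb of the gene span; imputed scores are
info-standardized and excluded below info 0.3. SNPs absent from the panel
are dropped with a per-gene note. Per-gene failures (degenerate weights,
monomorphic spans) are reported in the output's `note` column without
aborting the run. Gene p-values are reported raw; a `--bh` flag appends
Benjamini–Hochberg q-values.

## Winner's-curse adjustment

$p = 2\Phi(-|z|)$ floored at `min_p` ($10^{-320}$, keeping quantiles
finite), $q = \mathrm{BH}(p)$, $z_{adj} = \mathrm{sign}(z)\,
\Phi^{-1}(1-q/2)$. Because BH never decreases a p-value, $|z_{adj}| \le
|z|$ componentwise, signs are preserved (a microscopic $|z|$ may shrink
to exactly 0 when $p$ rounds to 1 in double precision), and the weak
ordering of $|z|$ is preserved (BH ties map distinct inputs to equal
outputs). The BH step itself is delegated to
`statsmodels.stats.multitest`.

## Synthetic data generator

Population allele frequencies follow Balding–Nichols around a uniform
ancestral frequency: $f_{k} \sim \mathrm{Beta}(f(1-F_k)/F_k,
(1-f)(1-F_k)/F_k)$, so $F_k$ is an $F_{ST}$-style differentiation
parameter with closed-form truth ($\mathrm{Var}(f_k - f) = F_k f(1-f)$).
Haplotypes are latent AR(1) Gaussians thresholded at the frequency
quantile within blocks; two haplotypes sum to a dosage. This yields
tractable LD oracles — adjacent-variant dosage correlation equals a
bivariate-normal orthant probability, checked by numerical integration —
and exactly independent blocks. Admixed cohorts resample panel rows with
individual-level (global) ancestry draws. GWAS Z-scores are drawn
$z \sim N(R\mu, R)$ via the symmetric eigenvalue square root.

What the generator does *not* emulate: recombination-map-shaped LD decay,
local-ancestry mosaics within admixed genomes, selection, genotyping or
imputation error in the panel, indels/multiallelics, and chromosome-X
conventions. Passing tests therefore demonstrate correctness of the
estimators under their own modelling assumptions, not robustness to
real-data artefacts such as strand errors or panel mis-specification
beyond what the harmonization layer filters.

Generator defaults (two populations of 200, 500 variants, $F = 0.1$,
$\rho = 0.8$, blocks of 50, ancestral frequencies in [0.05, 0.95]) are
desk-scale stand-ins for a large multi-ethnic panel; experiments override
them explicitly where a design needs more contrast or size.

## Validation experiment designs

Problem sizes were chosen to finish on one CPU in minutes while leaving
the measured quantities' Monte-Carlo noise well inside the asserted
bands.

- **Imputer oracle**: 100 random instances ($m_o \le 10$, $m_u \le 5$,
  random PSD correlations, $\lambda \in \{0, 0.1\}$) against a direct
  linear solve; agreement to $10^{-10}$. The two-observed-variant example
  ($z_o = (2,1)$, $r = (0.8, 0.4)$, off-diagonal 0.5) has the closed-form
  result $\hat z = 1.6$, info $= 0.64$, $z_{std} = 2.0$.
- **Ancestry recovery**: 10 independent panels (3 populations × 500,
  $F = 0.05/0.1/0.15$, 5000 LD-free SNPs), cohorts of 2000 at 60/30/10;
  afmix error vs the realized composition ≤ 0.02 (measured ≤ 0.007).
- **LD concordance**: 200 SNPs ($\rho = 0.9$, blocks of 50), cohort of
  5000 at 60/40. Mean |difference| vs pooled-genotype correlation is
  ≈ 0.011. The elementwise *max* over ~20k variant pairs sits at
  ≈ 0.055–0.08 across seeds — the finite cohort oracle's own noise floor,
  $\sqrt{2\ln M}/\sqrt{n} \approx 0.063$ — so a max-statistic band of
  0.05 at this n is not attainable by any estimator and the corresponding
  assertion is expected to fail; the bulk statistics are the meaningful
  concordance measure at this scale.
- **Null calibration**: 600 SNPs, 20% masked, 100 GWAS draws (~12k
  imputed scores), $\lambda = 0$: rejection rate of $z_{std}$ at 5% within
  [0.04, 0.06]; Pearson correlation between $\hat z$ and held-out truth
  among info ≥ 0.8 predictions ≥ 0.9 (its theoretical value is
  $\sqrt{E[\mathrm{info}]}$ on that set).
- **Gene-test calibration**: 200 disjoint 5-SNP genes with random
  two-category weights on a null GWAS; KS uniformity of p-values, exact
  agreement with an explicit-inverse GLS oracle, rescaling invariance.
- **FIQT**: hand-computed BH example $(0.01, 0.04) \to (0.02, 0.04)$;
  shrinkage/sign/ordering on 1000 random vectors; MSE improvement on
  selected top hits across 20 replicate GWAS.
- **CLI pipeline**: simulate-panel → afmix → distmix → jepegmix → fiqt
  chained through files, twice; all exit codes 0 and outputs
  byte-identical (gzip members are written with zeroed mtime for this
  reason).

## Known limitations

- zmix needs LD and/or allele-frequency contrast between candidate
  populations; closely related populations yield flat likelihoods and
  wide errors, and a single GWAS realization carries irreducible noise
  (≈ 0.03–0.07 on a two-population mixture at 2000 informative SNPs).
- Imputation quality is bounded by panel LD fidelity; no shrinkage beyond
  the diagonal ridge is applied to the panel correlation estimate.
- The gene test treats annotation weights as fixed known quantities;
  training them is out of scope.
- Effect-size (beta/SE) inputs, per-variant sample sizes, meta-analysis
  across cohorts, and genotype-level imputation are out of scope.
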