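# Methods

## Scope and model

The package implements a two-stage extreme-phenotype analysis: (1) de novo
mutation (DNM) discovery in parent–affected-offspring exome trios, and
(2) gene-level rare-variant burden testing of the discovered candidate
genes in an imputed case–control cohort, with a per-variant common-variant
scan alongside. Raw read alignment, the imputation HMM itself, and wet-lab
validation are outside scope: the artifact consumes (or simulates) VCF
genotype/depth evidence and genotype-probability matrices.

## Trio genotype caller

Per family member and site, read counts follow a binomial model: with
total depth d and per-read error ε, the alt-read count is
Binomial(d, θ_g) with θ = ε, ½, 1−ε for hom-ref, het, hom-alt. Posteriors
combine these likelihoods with Hardy–Weinberg priors when a population MAF
is annotated, otherwise a near-degenerate prior with P(het) = 10⁻⁴ and
P(hom-alt) = 10⁻⁸, reflecting that an unannotated alt allele is a priori a
rare or de novo event. A genotype is hard-called when its posterior
reaches 0.9, otherwise the member is a no-call; zero depth is always a
no-call. The 0.9 threshold is deliberately conservative; lowering it
admits more marginal candidates into the cascade but never past the
parental-trace rule.

## Filter cascade

Candidates are all (site, family) pairs where the child is called
het/hom-alt. Stages apply strictly in order, and a rejected candidate
never re-enters:

1. **NEPG removal** — the NGS-error-prone gene list is a required config
   input (the appropriate list is cohort- and pipeline-specific);
   intergenic sites pass.
2. **De novo pattern + parental trace** — child het, both parents hom-ref,
   and additionally zero alt reads in both parents. The trace rule is a
   strict count of raw alt reads, not a fraction: a single parental alt
   read rejects. Parents with no reads fail (absence of data is not
   absence of the allele).
3. **Non-silent** — missense, stop gain/loss, splice, frameshift or
   in-frame indel pass; synonymous, UTR, intronic and unannotated fail.

The cascade report stores entering/surviving counts and rejected sites per
stage; counts are monotone non-increasing by construction.

False-positive screening after the cascade: a candidate is flagged
*mosaic* when ≥1 unaffected sibling carries the alt allele (germline
mosaicism in a parent), and *psv_suspect* when a configured high-identity
paralog covers the position. Trios without siblings are left unflagged —
unknown is not evidence. Flags annotate rather than reject, matching how
such sites are resolved by orthogonal validation in practice.

## Synthetic trio generator

Emulates the statistical structure the cascade assumes, per family:
background polymorphic sites with MAF drawn log-uniform on
(5×10⁻⁴, 0.5) and Mendelian transmission; Poisson(dnm_rate) DNMs per
proband (default rate 1.0 — the expected one exonic DNM per individual),
injected as missense hets in non-NEPG genes; a mosaic_prob fraction of DNM
events (default 0.05) shared as a standard het with one unaffected
sibling; and Poisson(artifact_rate) paralog-artifact sites per trio
(default 0.1) confined to NEPG genes, where ~30% of reads carry the alt
allele in the child and one parent regardless of true genotype —
mismapping, not sequencing error, so they persist at ε = 0. Depth is
Poisson(mean_depth, default 60×); alt reads are Binomial(depth, θ_g). The
gene panel is a deterministic tiling of one synthetic chromosome (60 genes
× 3 exons × 300 bp by default), with a nepg_fraction (default 0.10)
flagged error-prone. Defaults follow the discovery design where stated
(30 trios, ~1 DNM/proband); depth, error rate, background site count
(1,500 — a desk-scale stand-in for a full exome's variant load), sibling
frequency and artifact rate are the package's own choices of realistic
values. What the generator does **not** model: linkage/haplotype
structure, X-chromosome inheritance, indel length distributions, batch or
capture effects, and mapping-quality covariates — so passing recovery
tests demonstrate the logic of the filters, not their operating
characteristics on real exomes.

## Info score and hard-calling

The info score is the standard ratio-of-variances measure
`1 − mean_i Var(g_i | triple_i) / (2p̂(1−p̂))`, p̂ the mean posterior
dosage halved, clamped to [0, 1] (raw values go negative when triples are
less informative than a binomial draw); a monomorphic p̂ defines score 1.
The cited imputation tool's exact formula is not printed in the source
study, so the documented metric family is adopted. Filtering order —
info ≥ 0.3 first, then hard-calling, then the >10% variant-missingness
removal (strict), then the ≥8% individual flag — was an open choice; info
is applied first because it is a property of the probabilities, not of
the calls. Individual missingness is a QC *flag* rather than an exclusion
because the source design reports it as an observed property of the
cohort, not a filter action.

The cohort generator draws probability triples from a Dirichlet centred
on the true genotype with concentration prob_certainty (default 2,000) on
the true component; a missing_rate fraction (default 0.02) is drawn
near-uniform (Dirichlet(30,30,30)). The high default concentration is what
reproduces a realistic info-score range: posterior dosage variance is
dominated by the small weight leaked to the hom-alt component, so at rare
sites (MAF ~0.2%) even a 2% symmetric leak drives info to 0. With 2,000
the simulated spectrum spans ~0.3–1.0 at rare sites and ~1.0 at common
sites, so the 0.3 floor removes a realistic minority of rare variants.
prob_certainty = ∞ yields exact one-hot triples (the noiseless limit used
in tests).

## Cohort disease model

Genotypes are independent Hardy–Weinberg draws per site (no LD — the
collapsing test operates on carrier indicators, which this does not bias).
Rare-site MAFs are log-uniform on (5×10⁻⁴, 0.01]; the spectrum is a
modeling choice, as no spectrum is specified by the design. Disease status
follows logit P(case) = logit(0.3) + log(carrier_or)·1{carrier in causal
gene} + Σ βc·z_c with independent standard-normal covariates (β = 0.1
each); cases and controls are filled by rejection sampling to exact
target sizes (defaults 4,036 / 6,995, mirroring the follow-up cohort).
Sub-phenotype labels are Bernoulli among cases at the configured
prevalences (defaults 0.3124 and 0.0461, mirroring the anti-dsDNA and
renal + hypocomplementemia subsets), with an optional per-label
(gene, odds-ratio) effect for power studies. carrier_or defaults to 2.0,
a plausible rare-variant carrier effect; it is a simulation parameter, not
an estimate from data.

## Burden statistic

The collapsing test uses carrier counts (not allele counts): the cited
tool's exact statistic is not recoverable from its description, and the
carrier 2×2 with a one-sided exact test is the fully specified,
oracle-testable reading of "one-tailed collapsing". The exact engine is
the hypergeometric upper tail P(X ≥ k) for k case carriers among K total
carriers, n_cases draws from N individuals; the permutation engine
shuffles labels (implemented as direct hypergeometric draws, which is
distributionally identical for a fixed binary carrier vector) with the
add-one estimator p = (b+1)/(B+1) to avoid zero p-values. Degenerate
markers (no qualifying site) return p = 1. Qualifying MAF is computed in
the combined analyzed sample — self-contained, with no external reference
— and missing hard calls count as non-carrier, which is conservative for
the one-sided alternative. Burden tests use no covariates; covariates
enter only the common-variant scan, matching the two tests' designs.
Sub-phenotype tests restrict cases to the label and reuse the full control
set. FDR (Benjamini–Hochberg, 5%) is applied across exactly the genes
tested in a run.

## Common-variant scan

Per variant with combined-sample MAF > 1%: additive logistic regression of
status on dosage plus four covariates, Wald p-value; if the fit fails or
does not converge (separation), the Rao score test against the
covariate-only null is reported instead — the score statistic exists under
separation, so no variant ever yields a failed test. Bonferroni threshold
is α/n_tests with n_tests an argument (3,000 by default, the convention of
the original region-wide scan; reported truncated to 3 significant
figures, 1.66×10⁻⁵).

## Numerical and degenerate-input choices

- Probability triples must sum to 1 within 10⁻⁶; hard-call ties at exactly
  0.5 are missing (strict inequality).
- Median over an even number of constraint scores is the mean of the two
  central values; absent scores are excluded, never imputed.
- ExAC absence is null ("not observed"), semantically distinct from 0.
- CpG detection uses the reference trinucleotide context only (CpG
  hypermutability is a property of the reference dinucleotide) and is
  strand-symmetric; without context the Ti classification stands and no
  upgrade occurs.
- Multiallelic VCF records are rejected with instruction to decompose.
- Coordinates: VCF/GEN 1-based, BED 0-based half-open; conversions live
  only in the IO layer.
- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical config + seed gives byte-identical
  output files and reports.

## Problem sizes in the shipped checks

The test suite and acceptance script run at desk scale by design: trio
simulations of 10–30 families with 150–1,500 background sites; null
calibration with 2,000 replicates at 500 cases / 500 controls; power at
carrier odds ratios {1, 2, 5} with 300 replicates each; the exact-engine
oracle over every 2×2 table with N ≤ 50. The headline cohort associations
of the motivating study (specific gene-level p-values in ~11,000
individuals) depend on non-deposited genotype data and are not targets of
these checks; what the checks establish is that every rule of the
procedure behaves as specified and that the statistical engines are
calibrated and correct against independent oracles.

## Known limitations

- One bespoke likelihood caller replaces the original three-caller
  consensus; the union/intersection bookkeeping of multiple callers is
  reproduced only as report structure.
- The NEPG gene list and paralog map are config inputs; no curated lists
  ship with the package.
- The burden engine is a burden-class test only; dispersion-style (SKAT
  family) tests, mixed models, and meta-analysis are non-goals.
- The synthetic cohort has no LD, no population stratification (covariates
  are independent of genotype by default), and no X-chromosome model.
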