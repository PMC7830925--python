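# Methods

`fibroprog` implements a comparative transcriptomics pipeline for panels of
independent knockout-vs-wildtype (KO-vs-WT) studies — the setting in which a
"common transcriptional program" is sought across several genetic models of
the same disease phenotype (here, liver fibrosis). This note documents the
statistical models, the tunable parameters, the synthetic-data generator that
defines the desk-scale study conditions, and the numerical choices.

## Differential expression

Each study is a genes × samples matrix of normalized log2 intensities with a
two-group design. Per gene the pipeline fits the ordinary two-sample
contrast

- effect: `β_g = mean(KO) − mean(WT)` (log2 fold change),
- residual variance: pooled within-group variance `s²_g` on
  `df = n_KO + n_WT − 2` degrees of freedom,
- design multiplier: `v = 1/n_KO + 1/n_WT`.

Variances are then shrunk toward a scaled inverse-chi-square prior
`σ²_g ~ s₀²·d₀/χ²_{d₀}` whose hyperparameters are estimated by moment
matching on `log s²` (mean and variance against the scaled-F implied by the
hierarchical model, using digamma/trigamma identities; the trigamma equation
is solved by Newton iteration). When the observed spread of `log s²` does
not exceed pure chi-square sampling noise, `d₀` is capped at 10⁶
("infinite" prior) and the scale falls back to the bias-corrected geometric
mean `exp(mean(log s²) − ψ(df/2) + log(df/2))`. Genes with `s² = 0` are
excluded from hyperparameter estimation but still receive moderated
statistics.

The moderated statistic is `t_g = β_g / sqrt(s²_post · v)` with
`s²_post = (d₀ s₀² + df s²_g)/(d₀ + df)`, referred to Student t on
`df + d₀` degrees of freedom, two-sided. Multiplicity is controlled by
Benjamini–Hochberg (via statsmodels); a gene is *up* or *down* only when
`fdr < α` (strict), with `α = 0.05` by default and no fold-change cutoff.
This stage was cross-checked against limma's `lmFit`/`eBayes` on a shared
simulated dataset and agrees to ~1e-14 in t, p and adjusted p.

## Parametric gene-set enrichment

Gene sets (pathway collections or transcription-factor target sets) are
filtered to members present in the expression matrix and to a minimum size
(default 5). Transcription-factor records sharing a factor ID are merged to
the union of their targets *before* size filtering, irrespective of binding
site.

Scores: each gene is converted to a per-sample log-ratio by subtracting the
gene's WT-group mean within the study; the activation score of a set with
`m` members in sample `j` is the one-sample t of the member ratios,
`mean·√m/sd`, with the standard deviation floored at `sd_floor = 1e-8` so a
set whose members move in lockstep still scores finitely. Inference then
reuses the gene-level machinery verbatim on the set × sample score matrix:
the KO−WT contrast of scores is the reported set "fold change", with
moderated t, BH-FDR and a pos/neg/ns direction.

**Known conservatism.** Because the reference is the WT-group mean computed
from the same WT samples, the WT group's score mean is close to zero by
construction, while the two-group test still charges the WT group its full
share of the variance. The second-stage t is therefore deflated by up to
√2, and the realized fraction of null sets with raw p < 0.05 is ≈ 0.02–0.03
rather than 0.05 at the default group sizes. The procedure is conservative,
not anticonservative: positive calls remain trustworthy, but power is lower
than nominal. This is intrinsic to scoring against an in-study reference
followed by a standard two-group contrast, and is retained deliberately
because it is the procedure the pipeline models; alternatives (leave-one-out
references, a one-group test on KO scores) would change the estimand.

## Cross-model comparison

Per model, significant genes and sets are partitioned by direction. Venn
region counts are exact over all non-empty model subsets (tables for up to
6 models). Similarity between models is summarized by the deliberately
non-symmetric ratio `pos[a,b] = |up_a ∩ up_b| / |up_a|` (analogously for
negative changes): each pair of models is characterized by two ratios, each
normalized row-wise by the row model's own count. The diagonal is defined
as 1 for non-empty sets; empty rows are reported as 0 with a flag rather
than NaN. For heat-map-style views, expression of a gene subset is scaled
per sample to zero mean and unit standard deviation, and genes/samples are
clustered agglomeratively (Euclidean distance, average linkage — the choice
is a package default, documented rather than inherited). Leaf order is made
deterministic by ordering children at each merge by (height, then
lexicographically smallest leaf label). Direction concordance against an
external reference table of enrichment signs (+/−/ns) excludes
reference-ns sets from the concordance denominator.

## Metabolic-model integration

A constraint-based model (stoichiometry, flux bounds, boolean GPR rules,
subsystem labels, one objective reaction) is read from a small JSON dialect.
Expression transitions are encoded per gene as `d ∈ {+1, −1, 0}` (sign of
the log fold change when fdr < α, else 0) with confidence weight
`w = −log10(p)` capped at `w_max = 10`.

The integration MILP assigns binary gene states per condition (WT, KO) to
maximize the weighted number of genes whose state transition matches `d`,
subject to, for each condition: reaction states equal to the GPR evaluated
on the gene states (AND = min, OR = max, linearized exactly with auxiliary
binaries), fluxes gated by reaction state with each reaction's own bounds as
big-M, steady-state mass balance `S·v = 0`, and objective flux at least a
fraction `f` (default 0.3) of the all-active FBA optimum. Decision
variables exist only for genes that appear in some GPR; expression genes
outside the model cannot constrain the network and are excluded from the
objective (their count is reported). Among match-optimal solutions, a
second lexicographic solve maximizes the number of active gene states
(tolerance 1e-7 relative on the match objective), so the conditions deviate
from the fully active reference only where the evidence demands it — this
also makes solutions reproducible across solver tie-breaking. All LPs and
MILPs run on SciPy's HiGHS interfaces; the MILP optimum was verified
exactly (50/50) against exhaustive enumeration over all gene-state pairs
with LP feasibility checks on random small networks.

Flux variability analysis then computes, per reaction and condition, the
min/max flux under the same functionality constraint (reactions with state
0 are reported as [0, 0] without solving). A reaction's capacity is
`max(|lo|, |hi|)`; it is classified *up* if the KO capacity exceeds the WT
capacity by more than `eps = 1e-6` and *down* in the opposite case, with a
state switch (on→off = down, off→on = up) overriding the capacity rule.
The classification criterion is the package's own, configurable choice —
the capacity comparison is simple and antisymmetric under condition swap.
Subsystems are tested separately per direction with the hypergeometric
upper tail `P(X ≥ k)` for `k` of the `n` direction-classified reactions
falling in a subsystem of size `K` out of `N`, BH-adjusted across
subsystems within the direction, significant at fdr < 0.05.

## Synthetic study conditions

The generator emulates a panel of independent KO-vs-WT microarray studies
on the normalized log2 scale. Defaults (the study conditions all recovery
tests use): 5 models, 2000 genes, 4 samples per group, baseline
`N(8, 1.5²)`, gene variances `σ²_g ~ s₀²·d₀/χ²_{d₀}` with `d₀ = 4`,
`s₀² = 0.04` (log2²), 50 commonly upregulated and 5 commonly downregulated
genes (the up/down asymmetry mirrors fibrotic-liver panels), 30
model-specific perturbed genes per model (half up, half down), all effects
±1 log2 unit. Baselines and variances are redrawn per model, emulating
independent studies on different platforms. Not emulated: probe-level
effects, normalization artifacts, batch or sex-specific effects (sex is
carried as metadata only), inter-gene correlation. Passing recovery tests
therefore demonstrates correctness of the statistical machinery under the
assumed hierarchical model, not robustness to real array artifacts.

Gene sets: the commonly upregulated genes are distributed over 5 planted
sets (default size 20, half planted members, the rest random unperturbed
fillers — i.e. all 50 planted genes are loaded), plus 40 decoy sets drawn
uniformly (sizes 10–30).

The toy metabolic network is a fixed, hand-curated liver-like fixture (19
metabolites, 28 reactions, 11 subsystems): glucose/fatty-acid/glutamate
uptake, glycolysis with a lactate outlet, pyruvate metabolism, a
five-reaction fatty-acid beta-oxidation chain, a short TCA segment,
glycogen/pentose-phosphate/nucleotide branches, and a biomass objective
consuming acetyl-CoA and oxaloacetate. The beta-oxidation genes are renamed
to the planted commonly-down genes, so a knockout that silences them loses
the fat-derived acetyl-CoA supply: the objective optimum drops from 10 to 6
(still feasible at `f = 0.3`), the five beta-oxidation reactions switch
off, and the subsystem is recoverable as significantly down. The network
is sized so that (a) the hypergeometric test retains resolution after BH
across 11 subsystems and (b) glycolytic capacities stay condition-symmetric
when beta-oxidation is off (the lactate outlet decouples glycolysis from
acetyl-CoA consumption); a separate random-network generator exists only
for fuzzing the MILP against enumeration. The fixture is versioned, not
random, so MILP tests are stable.

## Numerical choices and degenerate inputs

- `d₀` cap 10⁶ represents an infinite prior; with `d₀ = 0` (forced) the
  statistic reduces to the plain two-sample t, and genes with `s² = 0` then
  get p = 0 with a warning.
- BH ties are handled by the standard step-up running minimum.
- LP/MILP feasibility tolerances are HiGHS defaults; the functionality
  constraint carries a 1e-9 slack to avoid knife-edge infeasibility, and
  FVA intervals are clipped when solver noise inverts lo/hi by <1e-9.
- Constant sample columns in scaling are left centered with a warning;
  empty direction sets yield similarity 0 plus a flag.
- Venn tables refuse more than 6 models (the tabular output stops being
  interpretable).

## Problem sizes

Recovery and calibration checks run at the generator defaults above
(2000 genes, 4+4 samples, 20 replicates; 50 replicates of 200 decoy sets
for null calibration; 50 random MILP instances with ≤8 genes against
exhaustive enumeration). These sizes keep the full suite in the minutes
range on a single CPU while leaving the estimators in their intended
regime.

## Known limitations

- The enrichment stage's conservatism (above) costs power at small group
  sizes; with 4+4 samples a planted set of 20 genes at +1 log2 on half its
  members is recovered as positive in ≈99.4% of set×model calls, not 100%.
- The MADE-style integration is the two-condition variant only; multi-way
  designs and flux sampling are out of scope.
- The FVA up/down criterion compares interval capacity only; reactions
  whose interval shifts without changing capacity are reported unchanged.
- SBML import is not provided; models enter through the JSON dialect.
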