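# Methods

## Penetrance models

A penetrance model maps each genotype combination g (risk-allele counts, one
digit in {0,1,2} per locus) to a disease probability f(g).  Models are
parameterised on the odds scale, odds(g) = b·r(g), with a baseline odds b and
a pattern of odds-ratio factors r(g) that defines the model type:

| type      | loci | r(g) |
|-----------|------|------|
| additive  | 1    | ORᵍ (multiplicative per risk allele) |
| recessive | 1    | OR for g = 2, else 1 |
| xor       | 2    | OR when exactly one locus is heterozygous, else 1 |

The XOR pattern is the classic two-locus purely epistatic model: at allele
frequency 0.5 its single-locus marginal penetrances are flat, so only a
two-locus search can see it.

Heritability is the observed-scale (binary) variance ratio under
Hardy–Weinberg genotype probabilities P(g) at the model's risk-allele
frequency:

    K  = Σ_g P(g) f(g)                      (prevalence)
    h² = Σ_g P(g) (f(g) − K)² / (K (1 − K))

### Solving, and the OR/h² incompatibility

The odds parameterisation realises the target odds ratio *identically in b
and the allele frequency*, so the construction reduces to a one-dimensional
root find: choose b so that h²(b) equals the 0.05 target (the smaller of the
two roots is used, giving the lower-prevalence table).  The allele frequency
is not identified by the odds-ratio constraint; it is fixed at 0.5 for
disease loci — the same frequency as noise loci, so allele frequency leaks no
information about which loci are causal.

Holding the odds ratio at a small value bounds h².  For a two-class pattern
(recessive, XOR) with high-risk class probability q, the odds-ratio
constraint caps the penetrance gap Δ = f_high − f_low at
Δmax = (√OR − 1)/(√OR + 1) · ... numerically 0.101 (OR 1.5) and 0.172 (OR 2),
and h² = q(1−q)Δ²/(K(1−K)) ≤ Δmax², attained at q = 1/2, K = 1/2.  The
ceilings, maximised over b at allele frequency 0.5 (which is also the argmax
over frequencies in (0, 0.5]):

| structure        | OR 1.5  | OR 2    |
|------------------|---------|---------|
| additive         | 0.0200  | 0.0556  |
| recessive        | 0.0077  | 0.0224  |
| xor              | 0.0102  | 0.0294  |

Only the additive pattern at OR 2 can reach h² = 0.05.  `build_penetrance`
therefore raises an `InfeasibleModelError` by default when the target is
unattainable; with `on_infeasible="cap"` (used by the study grid) it returns
the maximum-heritability table of the requested structure, flags it with
`h2_capped=True`, and records the achieved value in `realized_h2`.  The
realized odds ratio is exact in every case.  The design alternative — holding
h² at 0.05 and letting the odds ratio float — would erase the odds-ratio
factor from the experimental design entirely (all two-class models would
collapse to the same contrast), so the odds structure was kept exact and the
signal capped.  Consequence to keep in mind when comparing against published
low-signal studies: five of the six submodels here carry h² between 0.008 and
0.029 rather than 0.05, so single-locus detection rates run somewhat lower.

## Data simulation

Each simulated individual is assigned to submodel 1 with probability
`weight1` (the mixture is at the individual level), genotypes at all 25 loci
are drawn independently under HWE (binomial(2, p); noise loci at p = 0.5,
configurable), and status is Bernoulli(f(g)) using the assigned submodel's
loci only — submodel-1 loci are pure noise within the submodel-2 stratum and
vice versa, which the tests verify by a stratified chi-square.  Case-control
ascertainment is rejection sampling: individuals are drawn in batches and
accepted while their class still needs filling, until exactly 500 cases and
500 controls (configurable) are held; a 10⁷-individual attempt cap turns a
degenerate scenario into an explicit `SamplingStallError`.  Disease loci
occupy the first 2 (or 4) columns; MDR's exhaustive search is
position-symmetric, so their placement is immaterial.

The 21-scenario grid crosses model type (additive, recessive, XOR), mixing
weights (50/50, 25/75) and per-submodel odds ratios (1.5, 2); scenarios 1–7
are additive, 8–14 recessive (2 disease loci each), 15–21 XOR (4 disease
loci).

What the generator deliberately does **not** emulate: linkage disequilibrium,
genotyping error, missing genotypes, covariates, population structure, or
evolutionary/forward-time sampling.  Passing tests therefore speak to the
behaviour of the validation strategies under clean heterogeneity, not to
robustness against real-data artefacts.

## MDR engine

Tabulation uses a mixed-radix cell index (first locus least significant) and
`numpy.bincount`; the batch path counts all C(K, s) combinations per
(partition × status) stratum in one pass.  Risk classification is integer
cross-multiplication (cases·n₀ ≥ controls·n₁), which makes the high-risk call
exact: a cell with cases and no controls is high-risk (ratio +∞), an empty
cell is low-risk (a 0 ratio lies below any positive threshold), and a ratio
exactly at threshold is high-risk — the dominant software convention for the
tie the verbal rule ("exceeding"/"below") leaves open.  All ranking ties are
broken by ascending lexicographic locus order, so every result is
deterministic.

## Internal model validation

**CV (m = 5).** Folds are stratified by class (round-robin within shuffled
classes, so fold class counts differ by at most one).  For each fold the
classifier is fit on the other four folds (threshold = training n₁/n₀) and
scored on the held-out fold.  The per-fold winner is, by default, the
combination with the best *training* balanced accuracy — the convention of
the canonical MDR implementations, including the R package this study design
follows; `SplitSpec(fold_winner_by="test")` switches to picking winners by
held-out accuracy instead.  Cross-validation consistency (CVC) counts the
folds a combination wins; the per-size winner maximises CVC (ties: higher
mean held-out accuracy, then lexicographic), and the final model across sizes
must maximise both mean prediction accuracy and CVC, parsimony deciding when
they disagree.

**3WS (2:2:1).** One stratified split (remainders from uneven division go to
the training part).  Stage 1 fits and scores every combination on the
training part and keeps the top x per size (x defaults to K = 25).  Stage 2
re-fits each survivor on the testing part alone and keeps the best per size;
stage 3 re-fits the per-size finalists on the validation part and the highest
validation balanced accuracy wins (ties: parsimony, then lexicographic).  The
three parts are treated as independent, as the design prescribes;
`refit_per_stage=False` instead carries the stage-1 risk labels forward.
Because each stage re-fits on its own (small) part and scores in-sample, the
richest model almost always looks best at stage 3 — the mechanism behind the
three-way split's false-positive inflation.

Both selectors count their classifier fits per size (`SelectedModel.n_fits`):
exactly m·C(K, s) for CV and C(K, s) + min(x, C(K, s)) + 1 for 3WS, which the
tests assert as the operation-count form of the ~5× speed claim.

**Permutation test** (optional): case/control labels are permuted preserving
n₁/n₀, the full selection re-runs per permutation, and
p = (1 + #{permuted accuracy ≥ observed}) / (1 + n_perm).

## Power evaluation

With true submodel loci L1 and L2: conservative ⇔ selected = L1 ∪ L2;
mod1/mod2 ⇔ L1 (L2) ⊆ selected; onlymod1/onlymod2 ⇔ selected = L1 (L2);
nofalse ⇔ selected ⊆ L1 ∪ L2 (MDR always returns at least one locus, so an
empty selection is an error, not a success).  Power is the percentage of
replicates meeting a definition per (scenario, method); the model-size mode
breaks ties toward the smaller size.

The factorial ANOVA takes the per-(scenario × method) power of each
definition as the response (42 observations) and fits main effects of
validation method, heterogeneity level, model type and odds-ratio class with
Type-II sums of squares (statsmodels OLS).  The odds-ratio factor is coded
unordered — {both 1.5, both 2, mixed} — because the ordered "2/1.5"
arrangement occurs only at 25/75 mixing and would otherwise be entangled with
the heterogeneity factor.  Published p-values for this design are treated as
directional benchmarks only; the response coding behind them is not
recoverable.

## Seeding and problem sizes

Every unit of work draws its seed from
`SeedSequence(master, spawn_key=(scenario, replicate, purpose))` with purpose
0 = simulation, 1 = CV split, 2 = 3WS split, so results are independent of
execution order and exactly reproducible; the runner is serial.

Scales used by the shipped entry points (the package's choices for a
single-CPU desk run): the acceptance script runs the two-locus grid at the
full 14 × 100 replication and the XOR grid at 7 × 20; the analysis drivers
default to 25 and 8 replicates; the in-suite acceptance checks share one
14 × 20 / 7 × 8 study.  A two-locus dataset analyses in ~30 ms with both
methods; a four-locus dataset in ~1.1 s (the C(25,4) = 12 650 quadruple
search dominates).

## Known limitations

* The OR/h² incompatibility above means the simulated signal is weaker than
  the nominal 0.05 for five of six submodels; CV's mean final model sizes run
  correspondingly low relative to the published 1.21/1.84, while the
  structurally driven 3WS sizes (1.9 / 4.0) are insensitive to it.
* The original study's penetrance tables are not recoverable, so agreement is
  assessed on summary statistics and directions, not table-level identity.
* No multiple-testing adjustment across the six power definitions (matching
  the original analysis), and no interaction terms in the ANOVA.
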