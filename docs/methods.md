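# Methods

## Model and procedure

`mirmod` treats regulatory-module discovery as a two-stage combinatorial
search over evidence assembled from matched expression profiles and
sequence-based target predictions.

**Inputs.**  An mRNA matrix and a miRNA matrix over the same samples
(normalized, log-scale), a two-level sample grouping, a TF/nTF class label
per mRNA feature, and two regulator→gene edge tables with binding scores in
(0, 1] (miRNA target predictions, MS; TF binding-site similarity, TS).

**Feature selection.**  A coefficient-of-variation filter removes the least
variable fraction of probes per matrix (default 25 %; CV = sd/|mean|,
computed label-blind over all samples — whether the filter should see the
group labels is not specified anywhere, and the label-blind choice avoids
selection bias toward the contrast being tested).  Differential expression
uses Welch's two-sample t-test per feature; users can substitute their own
per-feature p-values (e.g. limma's moderated t) through
`select_features(..., mrna_pvalues=...)`.  Benjamini–Hochberg adjustment
runs across all CV-surviving features of each matrix jointly; thresholds
apply per class: nTF genes at adjusted p < 0.001 (stringent, because nTF
genes form the bulk of the universe), miRNAs at p < 0.05 (a small miRNA
expression change can have large downstream effects), TF genes exempt
(functional TFs need not be differentially expressed).

**Correlation significance.**  Pearson correlations for the three pair
classes, with a permutation test: per permutation one shared sample shuffle
is applied to the mRNA-side member of each pair (miRNA profiles keep their
labels against shuffled mRNA labels; within-matrix pairs shuffle one
member).  The p-value is the fraction of `n_perm` shuffles (default 10,000)
whose statistic is at least as extreme as the observed one.  The test is
two-sided via |PCC| by default so that strong *negative* miRNA–mRNA
correlations — the signature of repression — are significant; a signed
one-sided mode exists (`two_sided=False`).  Zero p-values are reported as
plain proportions.  Pairs with p < `alpha` (default 10⁻⁴) are retained.

**Stage 1 — genetic algorithm.**  Chromosomes are binary inclusion vectors
over the selected gene universe, TF genes first so that crossover can act
separately on the TF and nTF segments.  Fitness is the mean |PCC| over all
C(k,2) included pairs, where only significant, not-retired pairs contribute
(others count 0).  Roulette-wheel selection (with replacement; uniform
fallback when all fitnesses are zero), per-segment one-point crossover
(uniform crossover available), independent bit-flip mutation, a random
immigrant replacing the worst chromosome with probability `p_new` per
generation, and elitism (the best-ever chromosome is copied into each
generation, making the stagnation-based termination well defined).  The run
stops at `max_generations` or after `stagnation_limit` generations without
best-fitness improvement (tolerance 10⁻¹²) and returns the best-ever gene
set.

**Stage 2 — local search.**  Candidate regulators are all miRNAs/TFs either
predicted to target a gene of the set or significantly correlated with one.
The initial solution takes the TF genes inside the set plus a random draw
of miRNAs at the cap size.  Each iteration proposes one change to M′ or T′
(class chosen 1:1): below the class cap, a uniformly chosen pool candidate
is added — or removed if already inside; at the cap, an inside member is
swapped with an outside candidate.  Moves are accepted only on strict
fitness improvement.  Because initialization fills M′ to the cap and at-cap
moves are swaps, |M′| stays at the cap — which matches the method's
reported modules having a constant miRNA count.  The gene set G′ never
changes.  Caps default to 1 % (miRNAs) and 4 % (TFs) of the candidate
pools, `ceil` with minimum 1; TF genes inherited from the coexpressed set
are exempt from the cap at initialization and count against it afterwards.

**Scores.**  All binding scores and significant absolute correlations are
min–max scaled into [0.5, 1] — one scaler per evidence type (|Cor| pooled
across the three pair classes, MS, TS), fitted once per discovery run over
the candidate universe and frozen across extraction rounds.  Absent
components stay exactly 0 so support categories remain detectable.  The
module fitness is `F = (MGI + TGI + Cor_M′)/N`; the final evaluation score
adds `Cor_R′` (nTF–nTF pairs) with N recounted.  N counts supported pairs
only: ordered regulator→gene pairs (so two TFs regulating each other count
twice, once per direction, exactly as the double sum in the TGI definition
reads), unordered pairs within M′ and within R′, and TF self-pairs are
excluded.  `Cor_M′`/`Cor_R′` count each unordered pair once.

**Iterative extraction.**  After each module, every mRNA–mRNA correlation
pair involving its genes is retired; retired pairs never re-enter any
fitness term, so later rounds cannot rediscover the same coexpression
structure.  miRNA-side pairs are *not* retired — miRNAs may recur across
modules, as regulators genuinely do.

**Evaluation.**  (a) 1,000 random control modules with identical class
counts, sampled uniformly from the selected universes; the separation
between module scores and the control distribution is the headline quality
check.  (b) A member-substitution permutation test: per round, s ~
DiscreteUniform{0..|G′|} members are replaced, class-preservingly, by
uniformly chosen outside candidates; p is the fraction of rounds whose
permuted score strictly exceeds the observed one.  The substitution budget
is shared across miRNAs and genes (the wording bounds s by the gene count
only; a shared budget with class-preserving replacement keeps the module
shape intact — the ambiguity is noted, not silently resolved).
(c) Interaction categories both / PCC-only / binding-only, whose counts sum
to N by construction.

## Tunable parameters

| Parameter | Default | Notes |
|---|---|---|
| `preprocess.drop_fraction` | 0.25 | CV filter fraction |
| `preprocess.alpha_ntf` / `alpha_mirna` | 0.001 / 0.05 | adjusted-p cutoffs |
| `correlation.n_perm` / `alpha` | 10,000 / 10⁻⁴ | permutation test |
| `ga.pop_size` | 100 | not prescribed by the method; standard for this chromosome length |
| `ga.init_fraction` | 0.02 | fraction of genes set in initial chromosomes |
| `ga.p_co` / `p_mu` / `p_new` | 0.7 / 0.001 / 0.01 | operator rates at the published operating point |
| `ga.max_generations` / `stagnation_limit` | 5,000 / 200 | termination |
| `ls.k1` / `k2` | 1 / 1 | binding vs. correlation weight (k₁ multiplies MS/TS) |
| `ls.mirna_cap_fraction` / `tf_cap_fraction` | 0.01 / 0.04 | regulator caps |
| `ls.negative_only_mirna` | off | only negatively correlated miRNA–gene |Cor| terms enter MGI |
| `pipeline.n_modules` | 10 | extraction rounds |
| `pipeline.n_random_controls` / `n_module_perms` | 1,000 / 1,000 | evaluation |

On the weighting: the method's score definitions put k₁ on the binding
scores and k₂ on the correlations, and its weighting experiments emphasize
raising the binding weight; both weights are exposed, and the
implementation follows the score definitions literally (k₁·MS + k₂·|Cor|).

### Desk-scale presets

The defaults above describe genome-scale inputs (thousands of candidate
genes).  `mirmod.presets` carries the operating point used by the test
suite and `scripts/acceptance.py` on desk-scale synthetic studies (~200
selected genes): `init_fraction=0.2`, `p_mu=0.004`, `p_co=0.9`, 3,000
generations with stagnation limit 600, and regulator caps of 25 % so the
per-module budget can accommodate the planted 3-miRNA/7-TF shapes.  These
were determined the way the method itself prescribes — vary one operator
with the others fixed, compare convergence and planted-block recovery —
because the genome-scale relative settings degenerate at this size (2 % of
200 genes is a 4-gene chromosome; 1 % of a 15-miRNA pool caps modules at a
single miRNA).

## The synthetic-data generator

Each planted module is a single-factor block: member expression =
loading·factor + N(0, σ²) noise, with the loading chosen so the expected
within-module |PCC| equals `rho` (rho = λ²/(λ²+σ²)).  miRNA members take
negative loadings (repressor signature).  Condition specificity enters
through the factor itself: its mean shifts by `de_effect` between groups
(alternating sign across modules), so members inherit a DE signal
proportional to their loading.  A configurable fraction of background
features gets an independent group shift — DE decoys that survive selection
without belonging to a module — and all features sit on positive per-feature
baselines so the CV filter behaves as it does on log-intensity data.  True
regulator→member edges get high binding scores; decoy edges appear at a
background rate with lower scores.

What the generator does **not** emulate: heteroscedastic probe noise, batch
effects, correlated regulator activity outside modules, overlapping
modules, heavy-tailed expression.  Passing recovery tests therefore show
that the search machinery finds the structure the model class assumes — not
that real tissue data satisfies those assumptions.

A realistic consequence of pooled-sample correlation worth knowing: any two
differentially expressed features are correlated across pooled samples
(shared group-mean axis), so the DE decoys form a diffuse ~|0.5|-correlation
web.  This is a property of real two-condition data too, and it is the main
source of difficulty for the coexpression search at desk scale.

## Numerical choices and conventions

- CV uses |mean| in the denominator; |mean| < 10⁻¹² is rejected with advice
  to shift or drop the feature.  Boundary ties resolve toward keeping the
  lexicographically smaller feature ID.
- Welch p-values with zero variance in both groups: 1 when means agree,
  0 otherwise.
- Degenerate scaling collections (max = min) map to 0.75, the midpoint of
  [0.5, 1]; scalers clip out-of-range values into their fitted range.
- Chromosomes with fewer than 2 genes have coexpression fitness 0; modules
  with N = 0 have score 0.
- Worst-chromosome ties during immigration replace the lowest index;
  GA improvement tolerance 10⁻¹²; local-search acceptance is strictly
  improving.
- All randomness flows from `numpy.random.Generator` objects seeded via
  `SeedSequence`; identical seeds give byte-identical reports.

## Known limitations

1. **The GA objective prefers minimal subsets.**  The average pairwise
   |PCC| of any homogeneous correlated block is maximized, on finite
   samples, by its single best pair, so a sufficiently patient optimizer
   shrinks gene sets toward pairs.  In practice the GA's population
   dynamics (growth pressure from mutation, weak late-stage selection)
   keep returned sets near block size, but run-to-run variance is real:
   on desk-scale planted data the best-matching module's gene-set Jaccard
   against the planted block typically lands between 0.6 and 0.95.  Users
   who need size-stable gene sets should treat the GA output as a seed
   region, not an optimum.
2. **The module permutation test is conservative.**  Permuted modules share
   members with the observed module (substitution count s ~ U{0..|G′|}),
   so their scores are positively correlated with the observed score and
   null p-values concentrate around 0.5 rather than being uniform.
   Significance calls at p < 0.005 are therefore valid but conservative;
   the random-control comparison is the sharper separation check.
3. Modules are disjoint in genes by construction (pair retirement), so
   overlapping regulation of one gene by two modules cannot be represented.
4. The correlation permutation test assumes exchangeable samples under the
   null; structured confounders (batch, covariates) violate this and are
   out of scope.
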