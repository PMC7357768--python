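# Methods

This note documents the models, conventions and numerical choices behind
`beenet`, in the spirit of a statistical software methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
do not themselves compute.

## Network construction

Records are specimen-level observations (bee species, plant species,
calendar year).  Period windows are inclusive on both ends (the default
windows 1930–1969 and 1990–2009 jointly cover each period without internal
gaps).  A link is established iff the (bee, plant) pair occurs at least
`min_pair_count` times within the period — the default of 2 drops
singletons, which in opportunistic data are as likely to be labeling or
identification noise as real interactions.  "Twice" is interpreted as ≥ 2
specimen records of the pair, not exactly two and not two distinct years or
collection events; record counts beyond the threshold are then discarded
because specimen counts confound interaction frequency with collector
effort, so matrices are strictly binary.  Species names are matched exactly
after whitespace and case normalization; no fuzzy synonymy is attempted
(archives of this kind are expert-validated upstream).  The managed
honeybee (*Apis mellifera*) is excluded by default because its occurrence
tracks beekeeping, not wild foraging; cleptoparasitic bees are retained
since binary visitation, not pollen transport, is the object.  Species left
without any qualifying link are absent from the matrices: observed networks
contain no isolates, an invariant every downstream formula relies on.

## Connectance and rarefaction

Connectance is C = N/(p·b).  Because C is strongly size-dependent, the
between-period comparison uses matrices rarefied to a fixed total richness
(default: the sum of the two periods' minimum per-guild richnesses).  Each
replicate draws species without replacement, drops rows/columns emptied by
the restriction (C would otherwise be deflated by isolates that observed
networks never contain), and recomputes C.  How the fixed total splits
between guilds is underdetermined by the total alone; we split
proportionally to the observed guild sizes, which keeps the rarefied matrix
shape comparable across periods, and expose the rule as a parameter.
Draws are made over name-sorted species positions so a fixed seed produces
the same replicate set regardless of matrix row/column order.  The two
rarefied samples are compared with a two-sided rank-sum
(Wilcoxon–Mann–Whitney) test: replicates of different periods are
independent, so the unpaired form applies.

## Bipartite modularity and its optimization

The score is Barber's bipartite modularity: only bee–plant pairs are
scored, with the degree-product null term kᵢdⱼ/N.  Q is exactly 0 for the
single-module partition (the null term telescopes), and 0.5 for two equal
disjoint complete blocks — both serve as exact regression anchors.

Optimization is simulated annealing with restarts:

* **moves** — random single-node reassignments (constant-time ΔQ via
  per-module degree sums), plus, with probability 0.02 per step, a whole
  module merge or a random bisection split; acceptance is Metropolis,
  exp(ΔQ/T);
* **temperature** — T₀ is calibrated per network so the median worsening
  move from a random partition is accepted with probability ½; geometric
  cooling at 0.995 per level down to 10⁻⁴·T₀, with 10·(number of nodes)
  moves per level; 5 independent restarts (defaults; a documented `light`
  schedule — cooling 0.96, 5·nodes steps, 2 restarts — is used for large
  replicate ensembles and for small or well-separated networks);
* **polish** — each restart ends with a deterministic greedy pass accepting
  only improving single-node moves to a fixed point, which provably never
  lowers Q;
* **fallback and ties** — the single-module partition (Q = 0) is always a
  candidate, so the reported Q is never negative; among equal-Q partitions
  the first found under the seeded run order is kept, making results
  reproducible bit-for-bit given a seed.  The number of module labels
  available to the optimizer is capped (default min(nodes, 30));
* the reported Q of a returned partition is always recomputed from scratch
  rather than trusted from the incremental bookkeeping.

The hot loops are numba-compiled; a full-schedule detection of a
50-species-per-guild network takes well under a second after JIT warm-up.

## Null models

The null family preserves both degree sequences exactly: checkerboard
(2×2 submatrix) swaps applied to the observed matrix.  Each replicate
burns in independently from the observed matrix with its own derived seed;
the default budget is 1000 × (edge count) attempted swaps, the common
sequential-swap convention (the margin-preservation property is exact per
swap and independent of the budget; the budget only controls mixing).
Matrices with no checkerboard unit (perfectly nested patterns) cannot be
shuffled and are returned unchanged with a warning.  Null significance is
reported two ways: SES against 1.96, and the empirical fraction of null
modularities at or above the observed one.  Null replicates are annealed
with the same schedule as the observed network by default; a lighter
schedule can be passed when thousands of replicates make the full schedule
the dominant cost.  The between-period modularity comparison forms each
period's per-replicate (M_obs − M_null) differences and rank-sum-tests the
two difference samples, which controls for the periods' different sizes.
A consistency check subsamples the denser period's links down to the
sparser period's count before re-detection.

## Species roles (c and z)

c and z are computed for bees (the guild whose specialization is at issue);
the machinery is symmetric and accepts either guild.  Conventions:

* the c denominator kᵢ is the species' total degree including cross-module
  links, so c ∈ [0, 1 − 1/M] for M modules;
* z standardizes the within-module link count over the *bee* members of
  the species' own module (guild-specific pooling), with the sample
  (n−1) standard deviation; some implementations use the population form,
  so a `ddof=0` switch is provided and documented.  z is missing — a
  value, not an error — whenever the module's within-module-degree
  variance is zero (including single-bee modules), and species without z
  are never classified as hubs;
* thresholds for "high" c and z are empirical quantiles (default 0.90,
  optionally 0.95) of the c and defined-z values pooled across all species
  and all null replicates, with modules *re-detected on each replicate*:
  the swaps destroy the observed structure, and the thresholds must
  reflect the coefficient values that incidental structure produces.
  Quantiles use linear interpolation between order statistics;
* classification: high c and z → network hub; high c only → connector;
  high z only → module hub; neither → peripheral; "high" is strictly
  greater than the threshold.  The classical fixed cutoffs (c = 0.62,
  z = 2.5) are available behind an explicit function for comparison but
  are not the default.

One consequence worth knowing: because shuffled replicates typically
fragment into more modules than a cleanly modular observed network, the
null c-quantile can exceed the observed ceiling 1 − 1/M, in which case no
observed species can qualify as a connector at that quantile.  This is a
property of null-quantile thresholds, not a defect.

Temporal comparisons use the one-tailed paired signed-rank test on species
present in both periods (direction: later period higher), and one-tailed
rank-sum tests for species that appeared or disappeared against the other
species of the same period.  Ties are handled by midranks with the normal
approximation and continuity correction for larger samples, exactly for
small tie-free ones (scipy's auto policy).  Degree–coefficient association
is the Pearson product-moment correlation on complete cases.

## Module characterization

Cross-period correspondence clusters modules as *bee species sets*: binary
module × species incidence, Jaccard distances, Ward agglomeration, tree cut
at the largest per-period main-module count.  A matched group must contain
exactly one module per period *and* have positive pairwise species overlap
(all within-group distances < 1); without the overlap requirement, Ward
would happily pair disjoint modules.  Main modules are those with ≥ 10 bee
species by default.  The dendrogram is exported as Newick.

Plant taxonomic homogeneity is the species-by-genus ratio of the plants
linked to a module's bees (genus from a taxonomy column or the binomial's
first token), compared against the ratios of the null ensemble's detected
modules.  Trait profiles report per-category proportions; bee proportions
are per species, plant proportions are link-weighted by default (each
bee–plant link contributes its plant once, so commonly visited resources
weigh more), with a per-species mode available — the two conventions
answer different questions and both are exposed.  Trait–specialization
tests: rank-sum for two-category traits, Kruskal–Wallis for multi-category
traits (categories with < 2 species dropped with a note), and a 30%
quantile regression of ITD on c (statsmodels' pinball-loss IRLS,
convergence tolerance 10⁻⁸, deterministic); a constant response
short-circuits to a flat line at that constant.

## Synthetic data

The generator emulates the statistical features of the real archive that
the pipeline's correctness depends on, with planted ground truth:

* **planted blocks** — bees and plants assigned round-robin to modules;
  within-block link probability `p_in` (default 0.25), between-block
  `p_out` (0.02); a `generalist_fraction` (0.15) of bees instead links
  uniformly everywhere at the block-averaged rate, preserving expected
  degree.  Generalists have no well-defined true module, so partition
  recovery tests set this fraction to 0; recovery is measured as adjusted
  Rand index against the planted labels;
* **turnover** — a fraction (default 0.65) of bee species is sampled in
  only one period, targeting the ~35% between-period species overlap
  regime of the study system;
* **sampling effort** — per-species log-normal weights (unit shape by
  default).  The historical archive documents no effort model; the
  log-normal is our stand-in for the strong right-skew of opportunistic
  collections, not inferred intent;
* **traits** — categorical traits drawn from a mixture of a module-modal
  point mass (weight = association strength) and a uniform background;
  ITD normal around module means pulled toward the global mean as the
  association weakens.  Association 0 gives exchangeable traits; 1 gives
  pure module profiles.  Plant genera are nested within planted modules so
  the species-by-genus ratio carries signal against nulls.

What the generator does *not* emulate — and what passing tests therefore do
not certify about real archives: spatial and collector bias, phenology of
sampling dates within years, abundance-weighted interaction intensities,
taxonomic revisions/synonymy, and drift of sampling methods across decades.

## Problem sizes in the shipped checks

The test suite and acceptance script run at sizes chosen to exercise every
property at high statistical resolution while staying comfortably
interactive: planted recovery on 20×30×3-module networks over 50 (tests)
or 20 (script) seeds with the full default schedule; margin preservation
over 1000 (tests) / 300 (script) swap replicates of a 50×80 fixture with a
100×-edges burn-in; SES type-I control over 50/30 random 15×20 networks
with 60 null replicates each under a reduced schedule; the c/z oracle over
100/60 random networks; temporal-shift detection over 100/60 paired
synthetic periods (cross-module linking raised from 0.02 to 0.12 at fixed
membership, an effect sized to be unambiguous for a 30-bee paired test).

## Known limitations

* Annealing is a heuristic: Q is a lower bound on the optimum, and very
  flat modularity landscapes (near-random networks) yield partitions whose
  membership is not meaningful even though Q ≈ 0 is correctly reported.
* SES assumes the null modularity distribution is roughly normal; with few
  null replicates the 1.96 rule runs slightly liberal (the empirical
  quantile is reported alongside for this reason).
* The historical Belgian matrices are not redistributable, so their
  observed modularities and key-species lists are not recomputable here;
  the published dimension table ships as input for the desk-reproducible
  arithmetic, and everything deeper is validated on planted synthetic data.
* Weighted (abundance) analyses, nestedness and other network-level
  indices are out of scope by design.
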