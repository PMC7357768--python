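# beenet

Module-based specialization analysis of binary plant–bee interaction
networks, built for century-scale opportunistic record archives: collections
of dated "bee X caught on plant Y" specimens accumulated by naturalists
without a standardized protocol.  The toolkit was designed around a
two-period comparison of the Belgian plant–wild-bee network (1930–1969 vs
1990–2009) and is intended for pollination ecologists asking *who are the
specialists, who are the generalists, and how do those roles shift over
decades?*

## What it computes

Starting from a record table (bee, plant, year), `beenet`:

1. **builds per-period binary networks** — a link between bee *i* and plant
   *j* exists iff the pair was recorded at least twice in the period
   (singletons are treated as possibly spurious); the managed honeybee is
   excluded by default; matrices are binary, never weighted by specimen
   counts;
2. **scores classical indices** — species degree and connectance
   *C = N/(p·b)* (with *N* links, *p* plant and *b* bee species), compared
   across periods on matrices rarefied to a common total richness;
3. **detects modules** — groups of bees and plants interacting more among
   themselves than with the rest — by simulated annealing of Barber's
   bipartite modularity

   *Q = (1/N) Σᵢⱼ (Aᵢⱼ − kᵢdⱼ/N)·δ(gᵢ, gⱼ)*,

   which is 0 for a single module or random wiring and approaches 1 for
   fully separated modules;
4. **tests modularity against degree-preserving null models** — repeated
   checkerboard (2×2 submatrix) swaps keep every species' link count fixed;
   significance is the standardized effect size
   *SES = (M_obs − M̄_null)/SD_null*, with SES > 1.96 flagging a
   significantly modular structure;
5. **classifies species roles** from the participation coefficient
   *c = 1 − Σₛ(k_is/kᵢ)²* (how evenly a bee's links spread across modules)
   and the within-module degree *z* (its link count into its own module,
   standardized over that module's bees): peripherals, module hubs,
   connectors and network hubs, with "high" defined by 90%/95% quantiles of
   c and z computed on the null ensembles;
6. **characterizes modules** — cross-period module matching by Jaccard
   distance + Ward clustering of bee membership, plant species-by-genus
   ratios against null, trait profiles (tongue length, sociality, nesting,
   lecty, flight period, body size as intertegular distance; flower type
   and flowering duration for plants) and trait–specialization tests
   (rank tests, Kruskal–Wallis, 30% quantile regression of ITD on c).

A synthetic-data generator (`beenet.synth`) plants known module structure,
species turnover and heavy-tailed sampling effort, so the whole pipeline is
testable against ground truth without the (non-public) historical database.

## Worked example

Generate a synthetic two-period record set and run the full study:

```python
from beenet import synth
from beenet.pipeline import RunConfig, run_pipeline, report_summary_json
from beenet.modularity import AnnealSchedule

spec = synth.SyntheticSpec(seed=11)          # 60 bees x 90 plants, 3 modules
net, truth = synth.generate_planted_network(spec)
synth.generate_records(net, truth, spec).to_csv("records.csv", index=False)

config = RunConfig(records_path="records.csv", n_null=100, n_rarefy=500,
                   main_module_min_bees=5,
                   null_schedule=AnnealSchedule.light(), seed=42)
report = run_pipeline(config, out_dir="run")
print(report_summary_json(report))
```

prints (abridged):

```
"modularity[1930-1969]": 0.540608,   "n_modules[1930-1969]": 6,
"modularity[1990-2009]": 0.499516,   "n_modules[1990-2009]": 6,
"SES[1930-1969]": 7.8487,            "SES_significant[1930-1969]": true,
"SES[1990-2009]": 4.7568,            "SES_significant[1990-2009]": true,
"persisting_c_p": 0.0440,
"persisting_z_p": 0.6954,
"n_key_species[1930-1969]": 4,
"n_key_species[1990-2009]": 5
```

Both synthetic periods are significantly modular (SES ≫ 1.96), and because
the generator seeds each period independently from the same planted blocks,
the persisting bees' participation coefficient *c* shifts detectably
(p ≈ 0.044, one-tailed paired test) while their within-module *z* does not
(p ≈ 0.70) — the signature the role analysis is built to detect.  The
dimension table of the same run shows the planted species turnover:

```
               1930-1969  1990-2009  both  pooled_unique  fraction_shared
bee_species           39         41    21             59            0.356
plant_species         86         79    76             89            0.854
interactions         250        255   115            390            0.295
```

`run/` holds every intermediate (adjacency matrices, partitions, null
modularity samples, role tables, key-species report, module dendrogram in
Newick) as plain delimited text.

The same stages are available from the shell: `beenet synth`, `build`,
`metrics`, `modules`, `nulls`, `roles`, `characterize` and `run --config
config.yaml` (see `beenet --help`).

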