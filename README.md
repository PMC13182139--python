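# quartetpol

Polarized quartet support analysis and exhaustive rooted clade-supertree
ranking for phylogenomic supermatrices.

## What problem this addresses

Rapid deep radiations — the palaeognath birds (ostrich, rheas, kiwi,
emu/cassowaries, tinamous, moa) are the textbook case — leave very short
internal branches flanked by long, rate-heterogeneous terminal branches.
Concatenated maximum-likelihood trees and coalescent species-tree methods
then disagree with each other and can both be misled by incomplete lineage
sorting and long-branch attraction. `quartetpol` is for researchers who
want to interrogate such datasets at the level where the signal actually
lives: it quantifies, for every outgroup-polarized four-taxon sample, how
much genuinely shared-derived signal supports each rooted alternative, how
much of that apparent support is expected homoplasy, and what the filtered
signal implies for the rooted arrangement of a small set of predefined
clades.

## The method in brief

Species are assigned to clades, one clade being the outgroup *O* (the
shipped palaeognath table has ingroup clades E, K, R, S, T plus chicken as
*O*). Every triplet of ingroup clades forms a clade-quartet with *O*, and
every choice of one species per clade a species-quartet (a, b, c | O) with
three rooted candidate topologies T(x), distinguished by the grouped pair.
For each topology,

- **Na(x)** — the number of strict synapomorphic columns: the grouped pair
  shares a state, the third ingroup taxon carries the outgroup
  (plesiomorphic) state, and the shared state is derived. Exactly 12 of
  the 256 nucleotide quartet patterns fall in each class.
- **Nc(x)** — the expected number of such columns arising by convergence,
  computed from GTR+Γ+I models fitted by maximum likelihood to the same
  subalignment under the two rival topologies (α initialised at 1,
  invariable proportion at 0.3; exact 256-pattern probabilities via the
  pruning algorithm).
- raw support **S(x) = Na(x) − Nc(x)**, clamped at 0 and normalised to
  s(x) ∈ [0, 1].

Two filters drop unreliable quartets: **DIST** (support distance
SD₁₂ = s(best) − s(second) below an optimised threshold L_DIST: best and
runner-up nearly tied) and **RISK** (Nc(best)/Na(best) above L_RISK: the
winner itself dominated by expected convergence). Retained quartets are
aggregated per clade-quartet by per-topology medians, and **all** (2n−3)!!
rooted binary clade trees (105 for five ingroup clades) are scored by
summing the medians of the triplet topologies each tree induces — an
exhaustive, heuristic-free ranking. External trees (published species
trees, ML results) can be placed within the same ranking.

A built-in simulator generates supermatrices with the structure the method
assumes — multispecies-coalescent gene-tree discordance on a known clade
tree, per-clade rate scalars for long-branch regimes, GTR+Γ+I sites — so
the whole pipeline is testable without any data download. See
`docs/methods.md` for the full model description and design rationale.

## Worked example

Simulate a small palaeognath-structured dataset with strong internode
signal (truth: tinamou-first, (O,(S,(T,(E,(K,R)))))), then analyse it:

```sh
$ quartetpol simulate --preset strong_signal --seed 7 \
      --n-loci 20 --locus-length 300 --out example_data
wrote 15x6000 supermatrix to example_data

$ quartetpol run --alignment example_data/supermatrix.fasta \
      --clades example_data/clades.tsv --out example_run
run complete: example_run
best clade tree: ((((K,R),E),T),S);
```

The best-ranked clade tree is the generating one. The ranking table shows
how far the alternatives fall behind (support is the sum over the ten
clade-quartets of the median support, each in [0, 1], for the topology the
tree induces — so 10 would be unanimous, perfect signal):

```
$ head -4 example_run/ranking.tsv
rank    newick              support       distance_to_best
1       ((((K,R),E),T),S);  8.074457415   0
2       ((((E,R),K),T),S);  7.691009535   0.3834478801
3       ((((E,K),R),T),S);  7.382733475   0.69172394
```

Per-clade-quartet medians reveal where the signal is clean and where it
conflicts — here the emu/kiwi/rhea combination (EKOR) retains 14 of 16
quartets and splits its support, while ostrich-containing combinations are
far more one-sided:

```
$ head -3 example_run/summaries.tsv
clade_quartet  n_retained  n_total  empty  median_x1  median_x2     median_x3
EKOR           14          16       False  0          0.30827606    0.69172394
EKOS           8           8        False  0.84279053 0.15720947    0
```

An externally proposed tree — say a tinamou-last arrangement — can be
located inside the same exhaustive ranking:

```
$ quartetpol score-tree --run-dir example_run "(S,(E,(K,(R,T))));"
tree: ((((R,T),K),E),S);
rank: 17 of 105
support: 5.38185
distance to best: 2.69261
```

Further outputs in the run directory: per-quartet scores with Na, Nc,
SD₁₂, RISK and filter status (`scores.tsv`), per-species rejection tables
with ≥80 %/100 % flags (`rejections*.tsv`), ternary plot coordinates for
the three-way supports (`ternary.tsv`), and a provenance log (`run.json`).

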