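# Methods

## The problem

Deep radiations that happened quickly — the palaeognath birds (ostrich,
rheas, kiwi, emu/cassowaries, tinamous and the extinct moa) being the
canonical example — combine very short internal branches with long,
rate-heterogeneous terminal branches. Concatenated maximum-likelihood
trees and coalescent species-tree methods then routinely disagree, and
both can be misled by incomplete lineage sorting (ILS) and long-branch
attraction (LBA). `quartetpol` takes the complementary route of asking a
small, explicit question — *which rooted arrangement of a handful of
predefined clades does the site-pattern signal actually support, and how
much of that signal could be homoplasy?* — instead of estimating one
global tree.

## The method

### Polarized quartets

Species are partitioned into clades, one of which is the designated
outgroup (in the shipped palaeognath table: emu/cassowary E, kiwi K,
rhea R, ostrich S, tinamou+moa T, and chicken as outgroup O). Every
triplet of ingroup clades plus the outgroup forms a *clade-quartet*
(C(k,3) of them); picking one species per clade gives the
*species-quartets* (|A|·|B|·|C|·|O| per clade-quartet; 176 for the
shipped table). For each species-quartet (a, b, c | O) three rooted
topologies are compared, distinguished by the grouped ingroup pair:
x1 = (O,(c,(a,b))), x2 = (O,(b,(a,c))), x3 = (O,(a,(b,c))).

### Synapomorphic signal Na

A usable column (all four characters unambiguous nucleotides) supports
the topology grouping (i, j) if and only if i and j share a state, the
third ingroup taxon carries the outgroup's state, and the shared state
differs from it — a strict shared-derived (synapomorphic) pattern with
the outgroup fixing polarity. Of the 256 possible nucleotide columns
exactly 12 fall in each topology's class, and the classes are disjoint.
Na(x) is the count of such columns. Columns where the third taxon
matches neither side are ambiguous about polarity and count for nothing
(a relaxed mode is deliberately not offered as a default; strictness is
what makes the polarity argument clean).

### Expected convergent signal Nc

Observed synapomorphy-like patterns can arise by parallel substitution.
To estimate how many, each topology is fitted to the subalignment by
maximum likelihood under GTR+Γ+I (pruning algorithm on the unrooted
quartet, 4 median-of-category gamma rates plus an invariable class,
free branch lengths). Because the data collapse to a 256-bin pattern
histogram, fit cost is independent of alignment length. Nc(x) is then
defined as

    Nc(x) = n_usable × mean over the two rival topologies y ≠ x of
            P(x-supporting pattern class | fitted model of y)

i.e. the number of x-supporting columns expected *when x is false*,
averaged over both rivals (a `risk_mode="max"` variant uses the worse
rival instead). This is a documented reconstruction of the
convergence-expectation idea; its meaning is pinned by Monte-Carlo
oracle tests that simulate under the rival models and count classified
columns.

Fitting details: α is initialised at 1 and the invariable proportion at
0.3; exchangeabilities start equal; branch lengths start from
JC-corrected pairwise distances; base frequencies are held at their
empirical (+F) values rather than free — the standard practical choice,
and it keeps the 3 × 176 fits per run cheap. Optimisation is bounded
L-BFGS-B on log/logit-transformed parameters with two jittered restarts
on reported non-convergence. The rate mixture is normalised so branch
lengths are expected substitutions per variable site; the same
convention is used by the simulator, so fitted and generating scales
agree.

### Support, RISK and DIST

Raw support S(x) = Na(x) − Nc(x); negatives are clamped to zero and the
clamped values normalised to s(x) ∈ [0, 1] summing to one. A quartet
with no positive raw support is *uninformative*. Two filters follow:

* **DIST**: support distance SD₁₂ = s(best) − s(second); quartets below
  a threshold L_DIST are discarded (best and second-best nearly tied).
* **RISK**: RISK = Nc(best)/Na(best); quartets above L_RISK are
  discarded (even the winner is dominated by expected convergence).
  Note that an informative quartet always has RISK < 1, because its
  winner must satisfy Na > Nc.

A quartet is retained only if SD₁₂ ≥ L_DIST **and** RISK ≤ L_RISK (both
inclusive); rejected quartets are dropped entirely — the second-best
topology never substitutes. Thresholds are optimised per clade-quartet
by grid search over the deciles of the observed SD₁₂ and RISK values
plus the endpoints {0, 1}, maximising

    (best-minus-second margin of the per-topology medians over the
     retained set) × sqrt(retained fraction)

subject to at least one retained quartet. Ties prefer the larger
retained set, then the *larger* equivalent L_RISK, then the smaller
L_DIST. Preferring the larger equivalent RISK threshold means an
ineffective risk filter reports the saturated value 1.0, which is how
heavily conflicted clade combinations (typical of the long-branch
regime) surface in the threshold report. The objective itself is a
design choice made where the design was genuinely open; its defining
behaviours (balanced retention, threshold saturation under conflict)
are what the tests pin down.

### Aggregation and exhaustive supertree ranking

Per clade-quartet, the retained quartets' normalised supports are
aggregated by the per-topology **median** (robust to outliers; medians
are deliberately not re-normalised, so clade-quartets with internally
conflicted signal contribute less than unanimous ones). All (2n−3)!!
rooted binary trees on the ingroup clades (105 for n = 5) are then
enumerated; each candidate tree earns, from every non-empty
clade-quartet, the median support of the rooted triplet topology it
induces on that clade-quartet, and trees are ranked by the total. For
complete clade-quartet coverage of a binary candidate this
induced-triplet criterion selects exactly the maximal compatible
quartet set, so no heuristic search or explicit biclique construction
is needed; equivalence with an independent MRCA-based scorer is tested
to 1e-12. Externally supplied trees (e.g. published species trees or ML
results) can be located inside the same ranking (`score-tree`).

## The synthetic-data generator

Real supermatrices of the relevant kind are emulated, not downloaded.
A scenario is an ultrametric rooted clade tree with internode lengths
in **coalescent units**, per-clade species counts, per-clade
substitution-rate scalars, and a GTR+Γ+I model. Gene trees are drawn
under the multispecies coalescent (k lineages in a species-tree branch
coalesce at rate k(k−1)/2 per unit); a lineage accrues expected
substitutions at mu × scalar per unit as it traverses each branch, so
ILS (internode length) and branch-length artefacts (rate scalars) are
controlled independently — the two explanatory factors the analysis is
meant to separate. Within-clade structure is a fixed shallow
caterpillar (0.05-unit steps): within-clade phylogeny is not analysed,
only clade-level signal. Sequences evolve per locus along the gene tree
with per-site gamma/invariable rates.

Defaults: 100 loci × 500 bp, mu = 0.012 substitutions/site per
coalescent unit (≈ 0.3 expected substitutions on the 12-unit
chicken-like root-to-tip path of the strong preset — deep but
alignable), model rates (1.2, 4.0, 0.8, 1.1, 4.5, 1) with
transition-heavy exchangeabilities, frequencies (0.30, 0.20, 0.20,
0.30), α = 0.7, p_inv = 0.25 — unremarkable values for avian noncoding
alignments. Three presets share the published clade sizes
(2, 4, 2, 1, 5 + single outgroup) and the tinamou-first truth
(O,(S,(T,(E,(K,R))))):

* `strong_signal` — internodes ≥ 2 coalescent units (little ILS);
* `lba` — internodes ≤ 0.1 with 5–6× rate scalars on the outgroup,
  tinamou-like and rhea-like branches (heavy ILS + LBA pressure);
* `polytomy` — internodes ≤ 0.01 (effectively a hard polytomy among
  the four non-ostrich clades).

What the generator does **not** emulate: indels and alignment error
(gaps arise only from missing-taxon padding), base-composition
heterogeneity among lineages, within-locus recombination, gene flow,
and locus-specific model heterogeneity. Tests passing on these
simulations therefore demonstrate correctness of the machinery and the
qualitative regime behaviour, not robustness to every real-data
pathology.

## Numerical and degenerate-case choices

* IUPAC ambiguity codes are preserved on read but treated as missing in
  all signal computations; fabricating fractional signal from partial
  ambiguity is avoided.
* A quartet needs ≥ 20 informative columns (configurable) to enter
  scoring; below that the three-way normalisation is unstable.
* Na(best) = 0 gives RISK = +∞ (always rejected). All-constant
  subalignments raise and the quartet is marked uninformative.
* Exact ties (best topology, best tree) break by canonical
  alphabetical/newick order and are logged.
* Pattern probabilities are computed via the reversible eigensystem;
  root placement does not affect likelihood (time-reversibility), so
  polarity lives entirely in the pattern classification.
* Tree enumeration is guarded to 2–8 clades ((2n−3)!! growth).

## Problem sizes used by the test-suite and acceptance script

Unit tests run on small matrices and a single-quartet scenario. The
integrative checks use 100 loci × 500 bp × 5 replicate seeds for
strong-signal clade-tree recovery and 60 loci × 300 bp for the
three-preset regime survey (SD₁₂ collapse under polytomy, rejection
concentration under LBA, RISK-threshold saturation); parameter-recovery
checks use 10⁵-site quartet alignments. These sizes are the package's
own choices for a thorough desk-scale validation.

## Known limitations

* The Nc estimator and the threshold-optimisation objective are
  reconstructions of ideas whose reference implementations are not
  public in detail; both are documented above and pinned by behavioural
  tests rather than by external number-matching.
* Empirical (+F) base frequencies are not re-estimated by ML.
* The exhaustive ranking is exact only up to 8 ingroup clades.
* One haploid sample per species; no within-clade inference.
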