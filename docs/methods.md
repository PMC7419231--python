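# Methods

## Genome representation

Genomes are signed marker (synteny-block) orders on named chromosomes,
linear by default, circular supported.  All rearrangement arithmetic is
done on the adjacency/telomere set — unordered pairs of marker
extremities plus unpaired chromosome ends — so genome equality is
structural: chromosome names, listing order and whole-chromosome flips
are irrelevant.  Base-pair coordinates exist only in the synteny-block
layer; the DCJ machinery needs order and sign alone.

## DCJ distance

The adjacency graph between two genomes over the same N markers takes
the elements (adjacencies and telomeres) of each genome as vertices and
draws one edge per marker extremity.  Components are cycles and paths;
with C cycles and I odd-edge paths, d = N − (C + I/2).  Path parity is
counted in edges, which makes I even and d integral; this convention is
pinned by an independent oracle test (breadth-first search over all
single-DCJ moves for n ≤ 6, 200 random pairs).  A transposition is not
a primitive: it is two DCJs (circular excision plus reintegration),
following the standard model.

Sorting scenarios are produced by greedy adjacency completion — each
missing target adjacency is created by the unique DCJ that frees its
two extremities, then leftover adjacencies at target telomeres are cut.
Each step reduces the distance by exactly one, so the scenario length
equals the distance; ties are broken lexicographically on the target
element, making scenarios deterministic.

## Median (ancestral genome) reconstruction

Bounds: lower = ⌈half-sum⌉ of the pairwise distances, upper = sum −
max.  The upper bound is attained by placing the median at the leaf
closest to the other two, so the heuristic (which starts from every
leaf) can never exceed it.

**Exact solver.** Branch-and-bound over perfect matchings (with
telomeres) of the 2N extremities.  Adjacencies present in all three
genomes are fixed first — such an adjacency always belongs to some
optimal median — and the remaining extremities are matched depth-first,
candidates ordered by leaf support.  Pruning uses an incremental
cycle/path count per leaf (union-find with rollback): with c closed
cycles, i closed odd paths and u undecided extremities,

    d(m, g) ≥ N − c − i/2 − u/2,

because each future extremity decision can add at most ½ to C + I/2.
The bound is exact once u = 0, so complete assignments cost nothing
extra.  Search stops early when the incumbent attains the global lower
bound (certified optimal); a configurable node budget (default 10⁶)
returns best-so-far with `optimal=False` and a flagged status when
exhausted.  Co-optimal solutions found within the budget are counted,
and ties are resolved toward the lexicographically least adjacency set.
Correctness is anchored by exhaustive enumeration (all matchings on
n ≤ 4, 50 random triples).

**Heuristic.** Steepest descent over DCJ moves that create an element
observed in at least one input genome, ranked by (new total, −leaf
support, lexicographic key); the support term selects, among equally
parsimonious moves, those agreeing with more inputs — in practice the
co-optimal median closest to the true ancestor.  Descents start from
each input genome and from the majority-graph genome (elements taken
greedily by support).  If the lower bound is not reached, a second
phase adds intermediate genomes along the deterministic pairwise
sorting paths (both directions, fractions 0.2–0.8) as extra starts and
move targets: optimal medians often contain "between" adjacencies
present in no input genome, which leaf-supported moves cannot create,
and the sorting-path intermediates supply exactly those.  Everything is
deterministic; no randomness is used.

Under the default simulation conditions (below) the heuristic attains
the lower bound in most trials and recovers the true ancestor within
DCJ distance 2 in ≈95% of histories; its total never exceeded the
number of DCJ operations actually applied in any of the 50 standard
trials.

## Synteny blocks from orthologue tables

Anchors are gene families with exactly one copy in each of the three
genomes (others are dropped with a logged count — the collapse of
triplicated subgenome copies to one orthologue per genome is left to
the upstream orthology call).  Pairwise chaining is sparse dynamic
programming over anchors per chromosome pair, strictly monotone in both
genomes, in both orientations, with two deliberate choices:

* **Gaps are measured in anchor ranks**, not raw gene indices.
  Fractionation thins the 1:1:1 anchor set far below gene density
  (at retention 0.70 × 0.49 × 0.42 ≈ 14% of families survive in all
  three genomes), so gene-index gaps would shatter chains at junctions
  where nothing rearranged; rank gaps (as in MCScanX-style collinearity
  tools) are scale-free under fractionation.  Default `max_gap_genes=5`
  ranks, `min_anchors=3`.
* **Chains are strand-concordant**: forward chains accept only anchors
  with matching strands, reverse chains only opposite strands.  Purely
  positional chaining absorbs the boundary gene of an inversion into
  the flanking chain; strand concordance keeps inversion breakpoints
  sharp.

Three-genome blocks are maximal runs of reference-ordered anchors
(reference = alphabetically first label) that lie in one chain against
each other genome; runs split at chain changes, chromosome changes and
rank gaps.  Per-genome orientation is the majority strand agreement
with the reference.  Blocks become signed markers via
(chromosome, start) sorting, and the painting table maps every extant
placement to the median chromosome carrying its block (BED-like output,
0-based half-open).

## Divergence dating

Ks values ≤ 0.001 are discarded (allelic noise), the rest
log-transformed.  A 1-D Gaussian mixture is fitted by EM for
k = 1..k_max: quantile-based means, pooled initial s.d., uniform
weights; three restarts (the first unjittered, later ones with
seed-derived jitter), relative tolerance 1e-8 on the log-likelihood,
200-iteration cap.  One dimension with quantile starts converges in
~10–20 iterations at the true k; over-parameterized k never converges
(components trade vanishing mass indefinitely) and is cut off by the
cap, which only depresses a likelihood that the selection criterion
penalizes anyway.  Model choice minimizes BIC = (3k − 1) ln n −
2 loglik; ties take the smaller k.  EM monotonicity is asserted on
every iteration of every fit.  Goodness of fit is a χ² test on binned
counts (bins with expected < 5 merged; dof = bins − 1 − (3k − 1)).
Peak ages are T = exp(μ)/(2r) in Ma; the synonymous rate r has **no
default** — published rates differ by lineage and calibration, so the
user must supply one.

Ultrametric placement: with per-leaf DCJ distances (d₁, d₂, d_out) the
root sits on the median–outgroup edge at x = (d_out − mean(d₁, d₂))/2,
equalizing root-to-leaf depths; the two ingroup branches are equalized
to their mean (for the published distances 26 and 28 this mean, 27,
puts the root 21.5/70 ≈ 31% of the way to the outgroup).  Offsets
outside [0, d_out] — non-clock-like data — are clamped with a warning.

## Simulator: what it emulates and what it does not

`SimulationConfig` defaults define the study conditions: 50 blocks on 8
linear chromosomes, branch operation counts (5, 5, 15) mimicking two
close lineages and one strongly rearranged outgroup-like lineage,
operation mix reversal 0.6 / translocation 0.2 / fusion 0.05 /
fission 0.05 / transposition 0.1 (intrachromosomal inversions dominate
plant comparative maps), retention (0.70, 0.49, 0.42) as observed for
the least/most fractionated subgenomes after the *Brassica*
triplication, and 100 gene families per block (the published analysis
averages ≈145 orthologues per block; 100 keeps tables compact while the
three-genome anchor intersection stays robust, ~14 anchors per block).

Rearrangement sites are uniform over the *genome*: reversal intervals
uniformly over all proper intervals, translocation/fission breakpoints
uniformly over all adjacencies, so long chromosomes receive
proportionally more breaks.  (The alternative — chromosome first, site
within it — piles repeated churn onto one- and two-marker chromosomes;
under that model even the exact median sits several DCJs from the true
ancestor in a third of histories, an estimation bias of the model, not
the solver.)  Whole-chromosome reversals are structural no-ops and are
resampled, as are otherwise inapplicable draws (logged).  At least two
gene families per block survive fractionation (forced, logged) so no
block becomes unobservable.

Simulated data are idealized in ways real data are not: gene
coordinates are evenly spaced, orthology is error-free, strands are
perfectly annotated, fractionation is independent per gene and genome
(no fractionation runs or bias toward one parental subgenome), and
there are no tandem duplicates or partially collapsed paralogues.
Passing recovery tests therefore demonstrates the correctness of the
chaining/median machinery under the stated rearrangement model, not
robustness to annotation noise or orthology error.

## Numerical and degenerate-input choices

* Marker universes must match exactly between compared genomes
  (no DCJ-indel model); violations raise errors rather than silently
  dropping markers.
* Empty chromosomes, empty genome sets, non-positive Ks after
  filtering, zero/negative clock rates, and mixtures with fewer than 50
  retained values are all rejected loudly.
* All randomness flows from integer seeds through independent
  `numpy` generators per sub-task; identical seeds give bit-identical
  genomes, tables, Ks samples and mixture fits.
* Circular intermediates can arise during median search and sorting;
  they are legal DCJ states and are reported in the final genome's
  topology if present.

## Known limitations

* The exact median solver certifies optima comfortably for desk-scale
  universes (tens of markers when the three genomes are similar); on
  hard instances the node budget returns a flagged best-so-far.  The
  heuristic carries no optimality guarantee beyond the upper bound,
  though it attains the lower bound in most simulated histories.
* Chaining assumes one orthologue per genome per family; tandem arrays
  and unresolved paralogues must be collapsed upstream.
* Block building requires exactly three genomes; k > 3 medians and
  phylogeny-wide ancestral labelling are out of scope.
* Divergence times inherit the strict-clock assumption and the supplied
  substitution rate; no rate uncertainty is propagated.
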