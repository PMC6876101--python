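# Methods

## Model

`oncowalk` scores genes for association with a specific cancer by network
propagation on a quadruple-layer heterogeneous graph.  The block adjacency

```
H = [[G, GM, GL, GC], [GMᵀ, M, ML, MC], [GLᵀ, MLᵀ, L, LC], [GCᵀ, MCᵀ, LCᵀ, C]]
```

couples four node layers — `n` genes, `m` miRNAs, `l` lncRNAs, `c` cancers —
through six bipartite association blocks.  The intra-layer blocks are: the
merged PPI ∪ pathway gene network `G`; k-nearest-neighbour similarity
networks `M`, `L` over the RNAs (functional similarity derived from each
RNA's disease associations against a precomputed disease–disease similarity
matrix; `k = 10` by default, mirroring typical curated-network densities);
and a cancer network `C` linking every cancer to its `k = 3` most similar
peers.  The underlying assumption is the standard one for propagation
methods: phenotypically similar diseases share functionally related genes,
so proximity to the seed set in the fused graph is evidence of association.

### RNA functional similarity

For RNAs with disease groups `D₁`, `D₂`,

```
sim(R₁,R₂) = ( Σ_{d∈D₁} max_{d'∈D₂} DSim(d,d') + Σ_{d∈D₂} max_{d'∈D₁} DSim(d,d') ) / (|D₁|+|D₂|)
```

The measure is undefined for an RNA with no disease annotation; such RNAs
enter their layer as isolated nodes.  kNN selection excludes
zero-similarity candidates (a zero-weight edge is invisible to row
normalization), symmetrizes by union (an edge exists if either endpoint
selects the other), breaks ties at the k-th position lexicographically for
determinism, and carries the similarity value as edge weight.  Binary
weights are available as an option; weighted is the default because row
normalization then preserves the similarity ordering among neighbours.

### Gene-layer transition

With `W_P`, `W_Path` the row normalizations of the PPI and pathway
adjacencies and `N(i) ∈ {0,1,2}` the number of networks in which gene *i*
has neighbours,

```
Initial_W_G(i,·) = (1/N(i))·W_P(i,·) + (1/N(i))·W_Path(i,·) + W_com(i,·)
W_G = row_normalize(Initial_W_G)
```

`W_com(i,j)` equals, for every merged-network neighbour `j` of `i`, the
maximum cancer-gene fraction among the protein complexes containing `i`
(zero for genes in no complex).  The `1/N` factor is applied per source row:
`N` measures the source node's evidence support, and any per-row constant
interpretation is equivalent after the final row normalization up to the
relative weight of the complex term.  `1/N` is taken as 0 when `N(i) = 0`
(possible in user-supplied data), leaving at most the complex contribution.
Complexes are reduced to members present in the gene index; complexes left
with fewer than two members are dropped, consistent with the catalog's
singleton filter.

### Global transition and the walk

The global operator scales each intra-layer transition by `1 − δ` and the
row-normalized bipartite blocks by `δ/3`.  As written, that recipe is
sub-stochastic whenever a node lacks couplings to some layer, so the mass is
reallocated per row: `δ` is shared equally among only the non-empty
inter-layer blocks of that row; if all three are empty the intra-layer block
keeps full mass; if the intra-layer row is empty the inter-layer blocks
share mass 1.  This is the convention under which the operator is a genuine
transition matrix; rows of fully isolated nodes stay zero (dangling).

The walk iterates `P(t+1) = (1−γ)·Wᵀ·P(t) + γ·P(0)` to the residual
threshold `‖ΔP‖₂ < 10⁻⁶` (cap 1000 iterations, error with the last residual
beyond it).  The transpose is deliberate: `W` is row-stochastic, so `Wᵀ`
propagates probability mass along edges and keeps `P(t)` a distribution on
a dangling-free operator; iterating `W` itself would not.

### Two rounds and score fusion

Round one seeds every cancer-associated gene, miRNA and lncRNA plus all
cancer nodes.  Restart mass is `η_i` per layer, uniform over that layer's
seeds; an entity associated with several cancers counts once.  Layers
without seeds have their `η` redistributed proportionally over the seeded
layers.  The top `k = round(σ·n)` genes (minimum 1; score ties broken by
identifier) survive into a reconstructed network: the induced gene subgraph
with its coupling rows, other layers untouched, and the gene transition —
including the complex feedback, still driven by the *global* cancer-gene
set restricted to survivors — rebuilt on the reduced index.  Round two
reseeds with one cancer node and its associated entities and walks the
reconstructed operator.

`Score = α·P¹ + (1−α)·P²` per gene, with `P² = 0` for genes discarded after
round one so that all `n` genes remain rankable (cross-validation needs a
score for every candidate).  `Rank_score(i) = #{j ≠ i : Score(i) >
Score(j)} / n` over the candidate universe; the strict inequality makes
constant score vectors map to zero and the statistic invariant under
monotone transforms.

Defaults `δ = 0.5`, `η_i = 0.25`, `γ = 0.6`, `σ = 0.6`, `α = 0.9` follow the
established operating point of this family of walks.

## Evaluation harness

Leave-one-out cross-validation withholds each gene–cancer association in
turn.  A leakage guard removes the withheld gene not just from that
association but from *every* seed set and from the cancer-gene set feeding
the complex feedback; without the guard the withheld gene's own label leaks
into the operator and inflates performance (the harness exposes the
guard-off mode precisely to document that ordering).  Records whose cancer
retains no associated gene, miRNA or lncRNA after removal are skipped: the
bare cancer node is not disease-specific evidence.  The candidate set of a
record is the withheld gene plus all genes without an association to that
cancer.

ROC pools withheld-gene rank scores (positives) against the rank scores of
globally never-associated genes from each record's own run (negatives);
equal scores share a threshold and the AUC is trapezoidal.  Top-*k*%
counts a record when the withheld gene's strict rank is within `k%` of its
candidate count.  Two reference scorers run through the same harness: a
single-layer walk on the merged gene network (RWR) and a two-layer
gene + cancer walk with a plain gene transition (RWRH).

## Synthetic bundles

The generator emulates the statistical shape of the curated inputs, not any
database's exact statistics.  Defaults (the standard benchmark condition):
300 genes, 40 miRNAs, 40 lncRNAs, 6 cancers; six disjoint 10-gene modules,
one per cancer; background gene networks with mean degree 5 per channel
(PPI, pathway) and within-module edge probability enriched 5×; planted
gene→own-cancer association probability 0.8 ("signal") against a 0.02
background probability per gene–cancer pair ("noise"); RNAs themed
round-robin to cancers, associated with their theme at the signal rate and
interacting with their theme's planted genes at the signal rate; 30
complexes of 3–8 members, half drawn from single modules; disease
similarity high (0.6–0.9) within consecutive pairs of cancers and low
(0.05–0.35) across.  One integer seed drives a single `numpy` generator, so
bundles are byte-reproducible.

The matched null keeps every layer size and expected count but draws all
associations and edges uniformly.  A separate single-cancer, label-shuffled
configuration calibrates the rank statistic: with one cancer, every LOOCV
candidate is a non-seed, the withheld gene is exchangeable with its
candidate pool, and its rank score is uniform up to the 1/n rank grid.
With several cancers that exchangeability is deliberately broken — genes
associated with *other* cancers sit in the candidate set and, being
round-one seeds, systematically outrank any withheld gene — so uniformity
is only a meaningful calibration target in the single-cancer design.

What passing on these fixtures does **not** show: recovery of real degree
distributions (curated PPI networks are heavy-tailed; the generator is
Erdős–Rényi plus planted blocks), identifier curation, or behaviour at
database scale (10⁴ genes); the fixtures validate the propagation and
evaluation machinery, not biological conclusions.

### Attainable AUC under association noise

Withheld records split into two populations: planted associations, which
the walk recovers almost perfectly (pooled AUC ≈ 0.99 on the default
condition), and background-noise associations, which carry no signal by
construction and score near chance (≈ 0.6).  The overall LOOCV AUC is their
mixture, `(1−f)·AUC_signal + f·AUC_noise` with `f` the spurious fraction of
the association table.  At the default rates `f ≈ 0.43`, which caps the
expected AUC near 0.85 (measured 0.849 ± 0.020 over ten seeds) *even for a
perfect ranker* — a useful reminder that label noise, not ranking quality,
bounds this benchmark.  Top-*k*% counts are similarly scale-bound at desk
size: seed genes of other cancers occupy ~16% of each candidate list (vs
~1% at database scale), so withheld genes rarely enter the top 15% even
when they beat every non-seed gene.

## Numerical choices

* Dense `numpy` linear algebra throughout: supported problem sizes are a
  few hundred nodes per layer, where dense operations beat sparse overhead;
  a full LOOCV of ~80 records runs in about a second.
* Row normalization leaves all-zero rows zero; re-normalizing an already
  stochastic row can perturb the last floating-point bit, so "exact"
  reduction identities hold to ~10⁻¹⁵.
* Convergence residual is the Euclidean norm; with `γ ≥ 0.1` the iteration
  contracts at rate `1 − γ` and reaches 10⁻⁶ in a few dozen steps.
* All orderings (layer node order, top-k selection, kNN ties) are
  deterministic — lexicographic where scores tie — so identical inputs give
  bit-identical outputs.

## Limitations

* Disease–disease similarity is consumed precomputed; computing it from
  phenotype/disease ontologies is out of scope.
* Association blocks are binary; the source-style databases provide
  unweighted associations.
* The complex feedback applies a gene's best complex ratio uniformly to all
  its neighbours (the per-source-gene reading); a shared-complex variant
  (ratio of the complex containing both endpoints) would be a different
  model.
* Exactly two walk rounds; no per-cancer tuning of `σ`.
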