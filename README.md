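# oncowalk

Prioritization of cancer-associated genes by a **two-round random walk with
restart** on a quadruple-layer heterogeneous network of genes, microRNAs,
lncRNAs and cancers.

Network-propagation methods rank candidate disease genes by their proximity
to known disease genes, but single-network walks see only one evidence
channel and start from few seeds.  `oncowalk` fuses several channels into one
walkable structure:

* a **gene layer** merging a protein–protein interaction (PPI) network and a
  pathway co-membership network, with protein-complex feedback;
* **miRNA** and **lncRNA layers** whose edges come from disease-based
  functional similarity (each RNA linked to its *k* most similar peers);
* a **cancer layer** linking each cancer to its nearest phenotypic
  neighbours in a precomputed disease–disease similarity matrix;
* six bipartite coupling blocks (gene–cancer, miRNA–cancer, lncRNA–cancer,
  miRNA–gene, lncRNA–gene, miRNA–lncRNA).

## The method

The walk iterates the restart equation

```
P(t+1) = (1 − γ) Wᵀ P(t) + γ P(0)
```

until ‖P(t+1) − P(t)‖₂ < 10⁻⁶, where `W` is a row-stochastic transition
matrix over all four layers: intra-layer moves carry probability `1 − δ` and
jumps to the other layers share `δ`.  The gene-layer transition fuses the
row-normalized PPI and pathway transitions (each weighted by `1/N(i)`, where
`N(i)` counts the networks gene *i* participates in) plus a complex-feedback
term: each gene's row is boosted by the best cancer-gene fraction among the
protein complexes containing it.

**Round one** seeds the walk with *every* cancer-associated gene, miRNA and
lncRNA plus all cancer nodes — restart mass `η = (η₁…η₄)` split across
layers — and keeps the top `σ·n` genes by stationary probability.
**Round two** rebuilds the network on those genes, reseeds it with the
entities of one specific cancer, and walks again.  The final score is

```
Score = α·P¹(∞) + (1 − α)·P²(∞)
```

and each gene's `Rank_score` is the fraction of candidates it strictly
outranks.  Defaults: `δ = 0.5`, `ηᵢ = 0.25`, `γ = 0.6`, `σ = 0.6`,
`α = 0.9`.

Evaluation is leave-one-out cross-validation: every known gene–cancer
association is withheld in turn, the pipeline reruns for that cancer (with
the withheld gene removed from all seed sets and from the complex-feedback
gene set), and the withheld gene is ranked among genes not associated with
that cancer.  ROC/AUC pools withheld genes against genes never associated
with any cancer; top-*k*% counts report how many withheld genes land in the
top *k* percent of their candidate set.

Because the curated source databases are not redistributable, the package
ships a seeded synthetic-bundle generator (`oncowalk.simulate`) that plants
cancer-gene modules, themed RNAs and cancer-enriched complexes, together
with a matched no-signal null — the whole method is testable offline.

## Worked example

```sh
python examples/loocv_benchmark.py
```

```
planted fixture | trwr: AUC = 0.890 over 41 records
planted fixture |  rwr: AUC = 0.693 over 41 records
   null fixture | trwr: AUC = 0.531 over 52 records
   null fixture |  rwr: AUC = 0.482 over 52 records
```

On a 120-gene planted fixture the two-round multilayer walk (`trwr`)
recovers withheld cancer genes far ahead of never-associated genes
(AUC 0.89) and clearly beats the single-layer baseline (`rwr`, AUC 0.69);
on the matched label-free null both sit near chance, as they should.
`examples/prioritize_genes.py` prints a per-gene score table for one cancer
and `examples/parameter_sweep.py` sweeps `γ`, `σ`, `α`.

The same workflows are available from the shell:

```sh
oncowalk simulate --out bundle/ --seed 7
oncowalk prioritize --bundle bundle/ --disease ca00 --out scores.tsv
oncowalk loocv --bundle bundle/ --out results/
oncowalk sweep --bundle bundle/ --out grid.tsv --gamma-grid 0.4,0.6 --alpha-grid 0.5,0.9
```

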