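# Methods

## Model and assumptions

The package operationalizes the modularity hypothesis of disease
genetics: genes whose mutations produce the same or similar phenotypes
tend to lie close together in molecular networks. Each data source is a
weighted undirected gene network — an interaction network taken as given,
or a K-nearest-neighbour (KNN) graph derived from gene–term annotations —
and proximity of a candidate to the known disease genes is measured by
the steady state of a random walk with restart (RWR) seeded uniformly on
the known genes. Because each source is noisy and incomplete, the
per-source rankings are fused: the discounted rating system (DRS)
averages log-discounted rating levels; its weighted variant (WDRS) lets
more predictive sources dominate; N-dimensional order statistics (NDOS)
scores the joint extremity of a gene's rank ratios under a null of
independent uniform rankings.

Key assumptions: edge weights are meaningful similarities (strictly
positive); a gene absent from a source carries no evidence from it, so
fusion adjusts the per-gene source count N rather than imputing a rank;
and the disease genes of one family are exchangeable seeds (no per-gene
confidence).

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| γ (restart probability) | 0.7 | probability per step of returning to the seeds; mid-range of the commonly examined 0.6–0.9 band, across which pooled AUC is empirically flat (checked by test) |
| L1 tolerance | 1e-10 | stopping rule for the RWR iteration; iteration cap 10,000 with a hard error on non-convergence |
| K (KNN graph) | 5 | neighbours per gene in annotation-derived graphs |
| B (rating levels) | 5 | equal-size rating bins per source; performance is insensitive between 2 and 10 |
| AUC weight floor | 0.7 | WDRS zeroes sources below this standalone AUC, then normalizes weights to sum 1 |
| controls per gene | 99 | size of the artificial candidate interval around each held-out gene |

IC uses the natural log; any base rescales all IC values by one constant,
which leaves KNN neighbour selection and the column-normalized RWR —
hence every downstream rank — unchanged (asserted by test).

## Numerical and procedural choices

- **Transition matrix.** M(j,i) = A(j,i)/d(i) with d the weighted column
  sum. Isolated nodes are removed first: they are unreachable, and a zero
  column would leak probability mass. A wholly edgeless network
  degenerates to a zero matrix, and the iteration renormalizes p each
  step (an exact no-op whenever M is column-stochastic on its support),
  so the steady state is then simply the restart vector.
- **Tie-breaking.** Equal steady-state probabilities, equal combined
  scores: lexicographic gene-id, ascending. Deterministic and
  permutation-invariant everywhere.
- **KNN symmetrization.** Union of directed selections (an edge exists if
  either endpoint chose the other); ties at the k-th similarity are all
  included. Zero-similarity pairs never create edges, so a gene sharing
  no informative term with anyone stays isolated and is treated as absent
  from that source.
- **Rating bins.** rating(r) = B − ⌊(r−1)B/m⌋ — exactly equal blocks when
  B divides m, rank 1 always in the top block. Inside fusion the same
  formula is applied even when a source covers fewer than B test genes
  (blocks degenerate but stay monotone with top rating B); the public
  `assign_ratings` rejects B > m.
- **WDRS missing data.** Weights are renormalized per gene over the
  sources covering it, the weighted analogue of DRS's adjusted N; with
  full coverage this equals a global weight normalization, under missing
  data it avoids penalizing genes absent from heavy sources for reasons
  of coverage alone. A gene covered only by zero-weight sources scores 0
  and ranks last. Weights may come from a user-supplied table or from
  per-source LOOCV AUCs computed by `per_source_weights`; note that using
  the same LOOCV both to set weights and to evaluate WDRS is mildly
  circular — for a strict protocol, derive weights on held-out families
  or supply an external table.
- **NDOS.** Rank ratios use each source's own available-gene count as the
  denominator. The recursion V₀=1, V_k = Σᵢ (−1)^{i−1}(ρ_{N−k+1}^i/i!)V_{k−i},
  Q = N!·V_N is validated against the N=2 closed form 2ρ₁ρ₂−ρ₁² and a
  Monte-Carlo dominance oracle (10⁶ sorted-uniform draws, 3-SE band).
- **ROC pooling.** One (rank-ratio, label) pair per prioritized gene,
  pooled with equal weight across records; AUC is the Mann–Whitney
  statistic (ties ½) computed from the trapezoidal ROC. Records with
  different per-record m pool on the common rank-ratio scale.
- **Controls.** Genomic-interval neighbours require genome coordinates,
  which the package does not model; by default each held-out gene gets 99
  seeded random non-family genes drawn from the union of network nodes.
  A custom control provider (e.g. a genomic-neighbour table) can be
  passed to `loocv_run`.

## Synthetic generator

`gen_fixture` plants `n_families` disease modules of `family_size` genes
in `n_genes`: the interaction source connects within-family pairs with
probability `module_density` (default 0.30) against a background of 0.02,
and three annotation tables give family members ~6 family-specific terms
(carried with probability 0.9) over 8 random background terms from a
150-term pool, from which 5-NN graphs are built. Per-source coverage
(0.93, 0.88, 0.84, 0.80) subsamples genes to mimic database
incompleteness. The default LOOCV problem size is one 8-gene family per
seed with 99 controls, i.e. 8 prioritizations of ≤100 genes per run.

`simulate_extra_source` emulates adding a data source at fixed candidate
set: m of the 100 test genes (cycling 66, 59, 57, 57) are covered and
ranked by a uniform random permutation, after which the known disease
gene's rank is overwritten by a draw from an empirical rank distribution
(the displaced gene takes its permuted rank, keeping a valid
permutation). The default distribution is a synthetic top-skewed
truncated geometric (p = 0.25 over ranks 1–100) standing in for an
observed table; supply your own `EmpiricalRankDistribution` to match real
sources.

What the fixtures do **not** emulate: genome coordinates and linkage
intervals (controls are random, not positional), scale-free degree
structure, annotation propagation through the ontology DAG, correlated
errors between sources, and per-interaction confidence scores. Passing
tests on these fixtures therefore demonstrates correctness of the
algorithms and the expected qualitative behaviour (informative modules
are recovered, uninformative fixtures give chance AUC, added informative
sources help), not real-data AUC levels.

## Known limitations

- Annotation similarity scores shared terms only; no ancestor
  propagation or graph-based semantic similarity (Resnik etc.), so two
  genes annotated with sibling terms score 0.
- The functional-similarity KNN graphs and the RWR assume one connected
  signal component; families spread over several components rank poorly
  in that source by construction.
- Wilcoxon comparison uses scipy's exact/normal-approximation switch;
  with very few families the p-value granularity is coarse.
- Operation counters, not wall-clock, carry the DRS/NDOS complexity
  comparison; absolute timings are hardware-bound and out of scope.
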