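# Methods

## Phylogenetic profiling model

The pipeline assumes that functional coupling between genes leaves a
signature in their conservation patterns: when a pathway loses its utility
in a lineage, its member genes degrade or disappear together.  The unit of
evidence is the best-hit bit score `P[a, b]` between query gene `a` and the
proteome of species `b`.  Bit scores below **20.4 bits** — the score at
which a BLAST e-value of 0.05 is reached at this search scale — are set to
0; zero encodes "no detectable homolog", which the method deliberately
treats as signal rather than missingness.

### Normalization (NPP)

Raw bit scores confound conservation with protein length (longer alignments
accrue more bits) and with species distance (every gene scores lower in a
distant proteome).  The transform used here is:

1. `P[a, b] / L(a)` where `L(a)` is the query protein length in residues;
2. a per-species z-score over all genes, with the **sample (n−1) sd**
   (stated so regression tests are bit-exact); zeros are included in the
   column statistics by default.

The z-score is the minimal transform with a provable guarantee: the output,
and every downstream Pearson correlation, is invariant to any positive
affine rescaling of a species column.  Any per-species effect that acts as
a location/scale shift — including an `exp(−λ·d)` distance decay — is
removed exactly.  A fractional-rank mode (`method="rank"`, ranks in (0, 1],
average for ties) is provided as a robustness alternative, invariant to any
strictly monotone per-column transform.  A `log2(1+x)` pre-transform is
exposed but off by default; whether the upstream pipelines z-scored before
or after a log transform is not externally fixed, so no test asserts its
effect.

Species columns with zero variance (e.g. a near-reference species where
every gene is retained at saturating score) carry no comparative signal;
they are dropped with a record in `dropped_species` rather than erroring.
If every column is degenerate the transform fails with "no informative
species" — this happens, by construction, for a noise-free loss-free
simulation.

### Ranking and candidate sets

For a query gene, Pearson `r` is computed against every other gene over the
selected species columns: all species, or one clade (profiles are still
normalized on the full panel; the clade restriction slices columns at
correlation time — the same convention for both scales).  Ordering is total
and deterministic: `r` descending, ties broken by gene id ascending.  Genes
whose filtered profile is constant have no defined correlation; they are
flagged and placed last with a `-inf` sentinel instead of being dropped, so
`top_k` set sizes stay predictable.  The query is excluded from its own
candidate set.  Network edges connect pairs with `r` **strictly** greater
than the threshold (default 0.7).

## Synthetic data generator

The generator emulates exactly the structure the method exploits, at a
scale where ground truth is known:

- a clade-structured species panel (default 60 species: 20 Mammalia,
  12 Vertebrata, 10 Metazoa, 10 Fungi, 8 Protista) with per-clade uniform
  distances from the reference, ranges ordered so closer clades sit nearer;
- planted modules (default 10 modules of 8 genes among 1000) whose members
  share one Bernoulli(`p_loss`) loss indicator per species; background
  genes draw independent indicators.  Loss is i.i.d. per species by
  default — sufficient to create the correlation signal profiling detects
  while keeping recovery tests analyzable; a clade-block option (one draw
  per module × clade) mimics lineage-level losses;
- retained scores `L(g)·β·exp(−λ·d_s)·max(0, 1+ε)`, `ε ~ N(0, σ)`:
  multiplicative Gaussian noise clipped at zero keeps scores non-negative;
- lost genes draw background-homology scores from an Exponential with mean
  `μ_bg`, giving a thin tail above the bit threshold
  (`P(score > 20.4) = exp(−20.4/μ_bg)`, ≈ 1.7 % at the default `μ_bg = 5`).

Default parameters: `p_loss = 0.35` (loss patterns informative over 60
species without starving any column), `β = 2` bits/residue, `λ = 0.5` per
distance unit (the most distant clade scores ~27 % of a mammal hit),
`σ = 0.1`, lengths uniform in 100–800 aa.  Karyotype bands are assigned
uniformly from a 40-band list; the synthetic drug table marks ~10 % of
genes druggable (the rough genome-wide rate of direction-annotated targets)
with 1–3 interactions each, a quarter of rows carrying a non-directional
type to exercise vocabulary filtering.

What the generator does **not** model: tree-structured (phylogenetically
autocorrelated) loss, gene duplication and paralog interference, length
evolution, alignment-specific score artifacts, or correlated band/function
structure.  Passing recovery tests therefore shows the statistical
machinery recovers planted co-loss modules under realistic noise — not that
real proteome panels are free of the confounders above.

## Candidate statistics

- **Overlap.** Two size-`k1`/`k2` lists from an `N`-gene universe share
  `k1·k2/N` genes in expectation; the exact upper-tail p comes from the
  hypergeometric distribution (scipy).  For the study-scale worked example,
  two 200-gene lists from 20,192 genes share 1.98 ≈ 2 genes by chance.
  When the two lists come from nested species panels they are not
  independent, so the p-value is a reference point rather than a calibrated
  test.
- **Band clustering.** The universe is every band-annotated gene;
  candidates without a band are excluded and counted.  The null redraws
  same-size candidate sets uniformly without replacement (B default 100,000
  for CLI runs, enough to resolve p < 1e-5; tests use B ≤ 2000).  Empirical
  p uses the add-one convention `p = (1 + #{perm ≥ obs}) / (B + 1)` —
  standard practice, avoids p = 0 — with BH FDR across tested bands.  The
  null preserves only set size, not gene length or band density covariates.
  Because per-band counts are integers, these p-values are *valid but
  conservative*: the attainable rejection rate at a nominal 0.05 is below
  0.05 by an amount that depends on the count lattice (roughly 0.02–0.04
  in the regimes tested here).  Conservative type-I control is the
  guarantee this implementation makes.
- **Chance druggability.** The same resampler counts
  `|random set ∩ positives|`; its mean matches the hypergeometric `n·K/N`.
- **Drug tiering.** A candidate is druggable if it has ≥ 1 interaction
  whose type is in the directional vocabulary (default: inhibitor,
  activator, agonist, antagonist, blocker, modulator — configuration-
  exposed, since directional-type whitelists differ between interaction
  databases).  Tier 1 = in both candidate sets, tier 2 = one set, with an
  `in_enriched_band` flag for genes in bands at q ≤ 0.05.

## Determinism and seeding

Every stochastic routine takes an explicit seed; there is no module-level
RNG state.  The pipeline's single mandatory seed is expanded per stage as
`(seed XOR crc32(stage_name)) mod 2^31`, so each stage is individually
reproducible.  Permutation sampling is vectorized in chunks whose size is a
fixed function of the universe size, keeping draws identical across runs.
All writers emit fixed-precision floats (6 significant digits) and sorted
JSON; a full re-run under one config is byte-identical.  Simulation scales
used in the shipped tests (panels of 120–1000 genes, 12–60 species,
permutation counts 10–20,000) were chosen to make the statistical checks
decisive at interactive runtimes.

## Numerical choices and degenerate inputs

- Correlations are computed from centered dot products and clipped into
  [−1, 1] to absorb rounding at the boundaries.
- Ties at the top-k boundary break lexicographically by gene id:
  determinism is preferred over any unstated historical rule.
- `best_hits` is idempotent, order-invariant in its input hits, and
  monotone in the bit threshold.
- A gene table with duplicate ids collapses to the longest protein per gene
  (ties: lexicographically smallest symbol) — the longest-isoform rule —
  with a warning count; the collapse is idempotent.
- Raising the bit threshold via `apply_threshold` is allowed; lowering it
  is not (the discarded information is gone).

## Known limitations

- Uniform permutation is the only band null; no covariate matching for
  band gene density or gene length.
- Mammal-only rankings reuse panel-wide NPP columns rather than
  re-normalizing within the clade; both conventions exist in the
  literature, and this one keeps the two scales directly comparable.
- No tree-aware contrasts or explicit regression of score on branch
  length; the affine-invariance of the z-score is the distance correction.
- Only Pearson correlation is offered as the profile similarity in v1.
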