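# Methods

## Model

`mirmix` clusters fixed-length miRNA seed sequences — by default the 6-mer
at positions 2–7 (1-based, inclusive) of the mature sequence — with a
finite mixture of position weight matrices. A PWM `W_i` is a 4×L
column-stochastic matrix over the base order (A, C, G, U); component `i`
emits bases independently per position, so a seed `x` has probability

    P(x) = Σ_i λ_i Π_v W_i[x_v, v],      Σ_i λ_i = 1, λ_i ≥ 0.

The model is fitted by EM. The E-step computes responsibilities

    z_mi = λ_i P(x_m|W_i) / Σ_j λ_j P(x_m|W_j)

in log space (log-sum-exp), so datasets up to 10^5 sequences never
underflow. The M-step sets `λ̂_i` to the mean responsibility and each PWM
cell to the responsibility-weighted base count, smoothed by an additive
pseudocount per cell:

    Ŵ_i[b,v] = (c + Σ_m 1{x_mv=b} z_mi) / (4c + Σ_m z_mi).

This is the unique maximizer of the expected complete-data log-likelihood,
so the marginal log-likelihood is non-decreasing across iterations (a
property the test suite checks on every fit). An alternative
`m_step_variant="literal"` update that re-weights the *current* matrix
entries by matching-base responsibility mass and renormalizes per column is
available for comparison; it is not an ascent update and is not the
default. Hard groups are the argmax responsibility per sequence, ties to
the lowest component index; empty groups are retained and reported, never
re-seeded.

After fitting, a seed's cluster is summarized by the component's consensus
string (per-column argmax, ties A<C<G<U) and per-column information
content, the text substitute for a sequence logo.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `n_components` (k) | — | number of PWM components |
| `pseudocount` | 1e-4 | additive smoothing per PWM cell (counts); 0 allowed, but unsmoothed zero entries can make sequences impossible under every component, which is an error |
| `tol` | 1e-8 | relative marginal log-likelihood improvement below which EM stops |
| `max_iter` | 500 | EM iteration cap per restart |
| `n_init` / `--restarts` | 1 / 10 | independent restarts; the maximum-likelihood fit is kept |
| `init` | `from_sequences` | draw k data windows and spread each into a PWM; `dirichlet` draws columns from Dirichlet(1) |
| `match_weight` | 0.7 | probability on the observed base when spreading a window into an initial PWM |
| `random_state` | 0 | master seed; restart r at k components uses the NumPy seed sequence `[random_state, k, r]`, so scans are reproducible end to end with no hidden global RNG |

Initialization windows are drawn from the input seed set itself by default;
an optional `background` pool can supply external sequences (e.g. genomic
6-mers). The in-package default keeps runs self-contained: initialization
only needs diverse realizable windows, and the restart mechanism, not the
pool, drives basin coverage. `match_weight` is a free design constant —
anything in (0.25, 1) yields a usable soft seed matrix.

Model selection over k (`scan_k` / `mirmix scan`) compares raw best-of-
restarts log-likelihoods with no complexity penalty and reports the full
(k, best log-likelihood) table; the raw-likelihood criterion has no
guaranteed optimum in k, which is why the table is always written for
inspection.

## Validation scores

Both scores operate on raw empirical base frequencies of a group's member
seeds (no pseudocounts), so perfectly conserved groups reach the exact
extremes:

* **Silhouette (Score_S)** `(β−α)/max(α,β)` in [−1, 1] with Hamming
  distance; `α` is the mean distance to co-members (self excluded), `β` the
  minimum over other non-empty groups of the mean distance to that group.
  Records in singleton groups score 0 by convention, as do records with
  `α = β = 0`. Undefined with fewer than two non-empty groups (reported as
  `NA` in summary tables).
* **Match score (Score_M)** in [0, 1]: the per-position information content
  `I(v) = Σ_b f_{v,b} log(4 f_{v,b})` (natural log, `0·log 0 = 0`) weights
  the frequency of the sequence's own base, normalized between the
  worst-case and best-case sequences under the same frequency matrix. A
  profile in which every column is uniform has a zero denominator; the
  score is then 0 with a degenerate flag. The same empirical-frequency
  profile is used for every grouping being scored (model-derived or
  reference families), so scores are comparable across grouping methods.

Global summary scores are means over all sequences, not means of group
means. Baselines: uniform random labels at the same k, and average-linkage
agglomerative clustering on Hamming distances cut to exactly k clusters by
merge order (deterministic). Reference-family enrichment reports, per
family, the group containing most of its members as `overlap/family_size`,
overlap ties to the lowest group index, with members absent from the
grouping counted in the family size and reported separately.

## Synthetic data generator

`sample_mixture` samples exactly the generative model above with known
truth. Two separation regimes: `random` (every PWM column from a symmetric
Dirichlet) and `planted_consensus` — k distinct consensus strings at
pairwise Hamming ≥ 3, with probability 0.85 on the consensus base and
0.05 elsewhere, giving well-separated identifiable components.
`write_fixture_fasta` embeds each seed at positions 2–7 of a 22-mer with
uniform random flanks, so pipeline tests exercise FASTA parsing and seed
extraction, mirroring real mature-miRNA input in shape. The generator does
*not* emulate phylogenetic correlation between related miRNAs, shared-seed
duplicates, species composition, or any flank signal — passing recovery
tests show the estimator recovers its own generative model, not that real
miRNA families satisfy that model.

One property of the planted regime matters when reading recovery numbers:
at match 0.85 and consensus separation of Hamming 3–4, roughly 1–2% of
sequences per close component pair are genuinely more probable under a
neighboring component than under the one that emitted them. Agreement with
the latent labels is therefore capped at the Bayes-optimal assignment
(adjusted Rand ≈ 0.90–0.96 depending on the consensus draw) for *any*
estimator. The acceptance script reports the fitted model's adjusted Rand
next to the Bayes-optimal one computed from the true parameters so the two
can be compared directly; the fitted value tracking the Bayes value is the
meaningful recovery result.

## Numerical choices

* Natural log everywhere; mixture marginals via log-sum-exp.
* Zero PWM entries yield −inf per-sequence log-likelihoods, never
  exceptions; only a sequence impossible under *every* component raises,
  with a message pointing at the pseudocount.
* Convergence: relative log-likelihood change < `tol` (the change may be
  an exact 0 at a fixed point, which also stops).
* Ties: argmax assignment and consensus both resolve to the lowest index;
  enrichment ties to the lowest group index.
* Model JSON stores floats at full round-trip precision, with an explicit
  `base_order` field; save → load → save is byte-stable.
* Problem sizes in the test suite and acceptance script (N ≤ 2000,
  100-instance ascent sweeps, 20-trial selection studies) were chosen to
  exercise each property at statistically meaningful scale while keeping a
  full run in tens of seconds.

## Known limitations

* The EM objective is multimodal; restarts mitigate but do not guarantee
  the global optimum. The scan table makes restart variability visible.
* Raw-likelihood model selection over k has no penalty; k at the top of
  the scanned range can win on flexible data.
* Ambiguity codes (N, R, Y, …) have no slot in a 4-letter PWM; records
  containing them are rejected (or skipped with `--skip-invalid`), never
  coerced.
* Seeds are clustered per-record: miRNAs sharing a seed are distinct
  records and will co-cluster trivially, which inflates cohesion scores
  for duplicate-heavy inputs by construction.
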