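# mirmix

Mixture-of-PWMs clustering of miRNA seed sequences.

MicroRNA target recognition is dominated by the seed region — nucleotides
2–7 of the mature sequence — so miRNAs with similar seeds tend to share
targets and functions. `mirmix` groups mature miRNAs into sequence-based
functional families by modelling their seeds with a finite mixture of
position weight matrices (PWMs): each of k latent families has mixing
weight λᵢ and a 4×L column-stochastic matrix Wᵢ over (A, C, G, U), and a
seed x has probability

    P(x) = Σᵢ λᵢ Πᵥ Wᵢ[xᵥ, v].

Parameters are estimated by EM (log-space responsibilities, responsibility-
weighted count updates with pseudocount smoothing, multiple random
restarts, likelihood-based selection over k). Groupings are validated with
two scores: a Hamming-distance silhouette, Score_S = (β−α)/max(α,β) ∈
[−1, 1], and the information-weighted matrix match score Score_M ∈ [0, 1]
long used for transcription-factor binding-site matrices, with per-column
information I(v) = Σ_b f_{v,b} log(4 f_{v,b}). Utilities compare any
grouping against random and hierarchical baselines and count reference-
family enrichment ("overlap/family_size" per family).

The library is organised around a scikit-learn style estimator,
`PWMMixture` (`fit` / `predict` / `predict_proba`, fitted attributes
`lambdas_`, `pwms_`, `labels_`, …), which composes with sklearn model
selection; `fit_em`, `scan_k` and friends are thin functional wrappers.
Intended users: small-RNA and regulatory-genomics researchers who want
sequence-derived miRNA families with per-family motif matrices, plus a
reproducible CLI for batch runs.

## Worked example

Simulate 300 seeds from 3 planted families, fit a 3-component mixture with
10 restarts, and inspect the outputs:

```sh
mirmix simulate --k 3 --n 300 --rng-seed 7 --out-dir demo_sim
mirmix fit --input demo_sim/fixture.fasta --k 3 --restarts 10 \
           --rng-seed 7 --out-dir demo_fit
head -4 demo_fit/assignments.tsv
cat demo_fit/group_scores.tsv
```

```
id      seed    group_index     max_responsibility
sim_1_0 UAACCC  2       0.999733
sim_0_1 UGGUGU  1       0.999789
sim_0_2 UGGUGU  1       0.999789

group_index     n_members       mean_score_S    mean_score_M
0       98      0.520265        0.869388
1       101     0.557562        0.863332
2       101     0.519637        0.863398
all     300     0.532610        0.865332
```

Each record lands in the group whose PWM makes its seed most probable;
`max_responsibility` near 1 means the assignment is unambiguous. Mean
Score_S ≈ 0.53 says members sit much closer (in Hamming distance) to their
own group than to the nearest other group; mean Score_M ≈ 0.87 says member
seeds are well represented by their group's frequency matrix. The fitted
model itself is in `model.json`:

```python
>>> from mirmix.mixture import load_model
>>> m = load_model("demo_fit/model.json")
>>> m.consensus_strings()
['UACUAU', 'UGGUGU', 'UAACCU']
>>> [round(x, 3) for x in m.lambdas_]
[0.325, 0.338, 0.337]
>>> round(m.final_loglik_, 3)
-1335.53
```

The three consensus strings are the recovered family motifs; the mixing
weights recover the planted equal family sizes. `mirmix scan` fits a range
of k and keeps the maximum-likelihood model; `mirmix score` computes the
score table for any grouping (including a reference family table);
`mirmix compare` counts family enrichment per group.

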