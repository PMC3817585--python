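"""Cluster-validation scores for seed groupings.

Two scores, both over the fixed-length seed strings:

* the silhouette ``Score_S = (beta - alpha) / max(alpha, beta)`` with
  Hamming distance — cohesion versus separation, in [-1, 1];
* the match score ``Score_M`` — the information-weighted similarity of a
  sequence to its group's base-frequency matrix, normalized between the
  worst and best sequences attainable under that matrix, in [0, 1]. The
  per-position information content ``I(v)`` down-weights mismatches at
  poorly conserved positions. This is the matrix-similarity score long used
  to scan for transcription-factor binding sites.

Also here: random and average-linkage hierarchical baseline groupings, and
reference-family enrichment counting.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform

from .pwm import encode_seed, encode_seeds, information_vector


@dataclass
class Grouping:
    """A hard partition of records into ``k`` indexed groups.

    ``labels[m]`` is the 0-based group of record ``ids[m]``; ``seeds`` is the
    optional aligned list of seed strings. Empty groups are allowed.
    """

    ids: list[str]
    labels: np.ndarray
    k: int
    seeds: Optional[list[str]] = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.ids) != len(self.labels):
            raise ValueError("ids and labels must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("record ids must be unique")
        if len(self.labels) and (self.labels.min() < 0 or self.labels.max() >= self.k):
            raise ValueError("group indices must lie in [0, k)")
        if self.seeds is not None and len(self.seeds) != len(self.ids):
            raise ValueError("seeds must align with ids")

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.ids, self.labels.tolist()))

    def nonempty_groups(self) -> list[int]:
        return sorted(set(self.labels.tolist()))


@dataclass
class GroupFrequencyProfile:
    """Empirical 4×L base frequencies of a group's member seeds."""

    freqs: np.ndarray
    n_members: int

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.n_members >= 1 and not np.allclose(
            self.freqs.sum(axis=0), 1.0, atol=1e-9, rtol=0.0
        ):
            raise ValueError("profile columns must sum to 1")


def hamming(seed_a, seed_b) -> int:
    """Number of mismatching positions between two equal-length seeds."""
    a = encode_seed(seed_a) if isinstance(seed_a, str) else np.asarray(seed_a)
    b = encode_seed(seed_b) if isinstance(seed_b, str) else np.asarray(seed_b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape[0]} vs {b.shape[0]}")
    return int((a != b).sum())


def hamming_matrix(seeds) -> np.ndarray:
    """Pairwise Hamming distance matrix of a seed set."""
    X = encode_seeds(seeds)
    return (X[:, None, :] != X[None, :, :]).sum(axis=2)


def group_frequency_profile(seeds) -> GroupFrequencyProfile:
    """Empirical per-position base frequencies of a seed set (no smoothing)."""
    X = encode_seeds(seeds)
    n, L = X.shape
    if n == 0:
        raise ValueError("cannot profile an empty group")
    counts = (X[:, None, :] == np.arange(4)[None, :, None]).sum(axis=0)
    return GroupFrequencyProfile(freqs=counts / n, n_members=n)


def silhouette_scores(grouping: Grouping, seeds) -> np.ndarray:
    """Silhouette ``(beta-alpha)/max(alpha,beta)`` per record, Hamming metric.

    ``alpha`` is the mean distance to co-members (excluding self); ``beta``
    the minimum over other non-empty groups of the mean distance to that
    group. Records in singleton groups score 0 by convention, as do records
    with ``alpha = beta = 0``.
    """
    labels = grouping.labels
    groups = grouping.nonempty_groups()
    if len(groups) < 2:
        raise ValueError("silhouette requires at least 2 non-empty groups")
    D = hamming_matrix(seeds).astype(float)
    N = len(labels)
    onehot = np.zeros((N, grouping.k))
    onehot[np.arange(N), labels] = 1.0
    sums = D @ onehot  # (N, k): total distance from each record to each group
    counts = onehot.sum(axis=0)  # (k,)

    scores = np.zeros(N)
    for m in range(N):
        own = labels[m]
        if counts[own] <= 1:
            continue  # singleton: score 0
        alpha = sums[m, own] / (counts[own] - 1)
        beta = min(
            sums[m, g] / counts[g] for g in groups if g != own
        )
        denom = max(alpha, beta)
        scores[m] = 0.0 if denom == 0.0 else (beta - alpha) / denom
    return scores


def silhouette_score(record_id: str, grouping: Grouping, seeds) -> float:
    """Silhouette of one record (see :func:`silhouette_scores`)."""
    idx = grouping.ids.index(record_id)
    return float(silhouette_scores(grouping, seeds)[idx])


def match_score(
    seed: str, profile: GroupFrequencyProfile, return_degenerate: bool = False
):
    """Information-weighted match of a seed to a frequency profile, in [0, 1].

    ``Score_M = [Σ_v I(v) f_{v,b(v)} − Σ_v I(v) f_v^min] /
    [Σ_v I(v) f_v^max − Σ_v I(v) f_v^min]`` with ``b(v)`` the seed's base at
    position ``v``. If every column is uniform the denominator vanishes; the
    score is then 0 and the degenerate flag is set.
    """
    f = profile.freqs
    codes = encode_seed(seed) if isinstance(seed, str) else np.asarray(seed)
    if codes.shape[0] != f.shape[1]:
        raise ValueError(
            f"seed length {codes.shape[0]} does not match profile width {f.shape[1]}"
        )
    info = information_vector(f)
    f_obs = f[codes, np.arange(f.shape[1])]
    lo = float((info * f.min(axis=0)).sum())
    hi = float((info * f.max(axis=0)).sum())
    denom = hi - lo
    if denom == 0.0:
        return (0.0, True) if return_degenerate else 0.0
    score = (float((info * f_obs).sum()) - lo) / denom
    return (score, False) if return_degenerate else score


def group_summaries(grouping: Grouping, seeds):
    """Per-group and global mean scores.

    Returns ``(table, global_means)``: ``table`` has one row per non-empty
    group with columns ``group_index, n_members, mean_score_S,
    mean_score_M``; ``global_means`` holds the means over all sequences
    (not means of group means). With fewer than two non-empty groups the
    silhouette is undefined and reported as NaN.
    """
    seeds = [getattr(s, "seed", s) for s in seeds]
    labels = grouping.labels
    groups = grouping.nonempty_groups()
    if len(groups) >= 2:
        sil = silhouette_scores(grouping, seeds)
    else:
        sil = None

    X = encode_seeds(seeds)
    match = np.empty(len(seeds))
    for g in groups:
        members = np.flatnonzero(labels == g)
        profile = group_frequency_profile(X[members])
        for m in members:
            match[m] = match_score(X[m], profile)

    rows = []
    for g in groups:
        members = np.flatnonzero(labels == g)
        rows.append(
            {
                "group_index": g,
                "n_members": len(members),
                "mean_score_S": float(sil[members].mean()) if sil is not None else math.nan,
                "mean_score_M": float(match[members].mean()),
            }
        )
    table = pd.DataFrame(rows)
    global_means = {
        "n": len(seeds),
        "mean_score_S": float(sil.mean()) if sil is not None else math.nan,
        "mean_score_M": float(match.mean()),
    }
    return table, global_means


def random_grouping(record_ids, k: int, rng_seed: int, seeds=None) -> Grouping:
    """Assign each record uniformly at random among ``k`` groups (seeded)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(rng_seed)
    labels = rng.integers(0, k, size=len(record_ids))
    return Grouping(ids=list(record_ids), labels=labels, k=k, seeds=seeds)


def hierarchical_grouping(seeds, k: int, ids=None) -> Grouping:
    """Average-linkage agglomerative baseline on Hamming distances.

    The dendrogram is cut to exactly ``k`` clusters by merge order
    (deterministic; equal-height ties resolve by scipy's stable merge
    ordering on lowest indices).
    """
    seed_strings = [getattr(s, "seed", s) for s in seeds]
    N = len(seed_strings)
    if N < k:
        raise ValueError(f"cannot cut {N} records into {k} clusters")
    if ids is None:
        ids = [getattr(s, "id", f"seq_{m}") for m, s in enumerate(seeds)]
    D = hamming_matrix(seed_strings).astype(float)
    Z = linkage(squareform(D, checks=False), method="average")
    labels = cut_tree(Z, n_clusters=k).ravel()
    return Grouping(ids=list(ids), labels=labels, k=k, seeds=seed_strings)


def enrichment(grouping: Grouping, families) -> pd.DataFrame:
    """Best-group overlap of each reference family with the grouping.

    For each family: the group holding most of its members, the overlap
    count, the family size (including members missing from the grouping,
    which are also reported in ``n_missing``), and the display string
    ``"overlap/family_size"``. Ties in overlap go to the lowest group index.
    A family with no member present in the grouping is an error.
    """
    entries = getattr(families, "entries", families)
    label_of = grouping.as_dict()
    rows = []
    for family_id in sorted(entries):
        members = entries[family_id]
        present = [m for m in members if m in label_of]
        missing = sorted(set(members) - set(present))
        if not present:
            raise ValueError(
                f"family {family_id!r} has no member in the grouping; "
                f"missing members: {missing}"
            )
        tally = Counter(label_of[m] for m in present)
        best_count = max(tally.values())
        best_group = min(g for g, c in tally.items() if c == best_count)
        rows.append(
            {
                "family_id": family_id,
                "best_group": best_group,
                "overlap": best_count,
                "family_size": len(members),
                "n_missing": len(missing),
                "enrichment": f"{best_count}/{len(members)}",
            }
        )
    return pd.DataFrame(rows)
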