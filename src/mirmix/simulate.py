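"""Seeded synthetic seed-set generator for a known mixture of PWMs.

Samples exactly the model the clustering assumes: a component is drawn from
the mixing weights, then bases are drawn independently per position from
that component's PWM. The known truth (PWMs, weights, labels) rides along so
parameter-recovery and label-agreement tests can compare against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .io import SeedRecord
from .pwm import BASES, decode_seed, encode_seed

FIXTURE_TOTAL_LENGTH = 22  # typical mature miRNA length
SEED_START = 2  # 1-based; the seed occupies positions 2..7


@dataclass
class SimulationTruth:
    """A sampled dataset together with the generator that produced it."""

    true_pwms: np.ndarray  # (k, 4, L)
    true_lambdas: np.ndarray  # (k,)
    labels: np.ndarray  # (n,) true component per record
    seeds: list[SeedRecord]
    rng_seed: int

    @property
    def k(self) -> int:
        return self.true_pwms.shape[0]

    @property
    def L(self) -> int:
        return self.true_pwms.shape[2]


def _planted_consensus_pwms(
    k: int, L: int, match: float, min_hamming: int, rng: np.random.Generator
) -> np.ndarray:
    """PWMs from k distinct consensus strings at pairwise Hamming >= min_hamming."""
    if k > 4**L:
        raise ValueError(f"cannot plant {k} distinct consensus strings of length {L}")
    chosen: list[np.ndarray] = []
    for _ in range(100_000):
        cand = rng.integers(0, 4, size=L)
        if all(int((cand != c).sum()) >= min_hamming for c in chosen):
            chosen.append(cand)
            if len(chosen) == k:
                break
    else:
        raise ValueError(
            f"could not place {k} consensus strings at pairwise Hamming "
            f">= {min_hamming} for L={L}"
        )
    pwms = np.full((k, 4, L), (1.0 - match) / 3.0)
    for i, cons in enumerate(chosen):
        pwms[i, cons, np.arange(L)] = match
    return pwms


def sample_mixture(
    k: int,
    L: int = 6,
    n: int = 1000,
    lambdas=None,
    column_concentration: float = 1.0,
    separation: str = "random",
    rng_seed: int = 0,
    match: float = 0.85,
    min_hamming: int = 3,
) -> SimulationTruth:
    """Sample ``n`` seeds from a k-component PWM mixture with known truth.

    ``separation="random"`` draws every PWM column from a symmetric
    Dirichlet(``column_concentration``); ``"planted_consensus"`` builds the
    PWMs from k distinct consensus strings (pairwise Hamming >=
    ``min_hamming``) with probability ``match`` on the consensus base —
    well-separated, identifiable components. Deterministic per ``rng_seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if column_concentration <= 0:
        raise ValueError("column_concentration must be > 0")
    rng = np.random.default_rng(rng_seed)
    if lambdas is None:
        lambdas = np.full(k, 1.0 / k)
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.shape != (k,) or np.any(lambdas < 0) or abs(lambdas.sum() - 1) > 1e-9:
        raise ValueError("lambdas must be a length-k probability vector")

    if separation == "random":
        pwms = np.stack(
            [
                rng.dirichlet(np.full(4, column_concentration), size=L).T
                for _ in range(k)
            ]
        )
    elif separation == "planted_consensus":
        pwms = _planted_consensus_pwms(k, L, match, min_hamming, rng)
    else:
        raise ValueError(f"unknown separation mode {separation!r}")

    labels = rng.choice(k, size=n, p=lambdas)
    codes = np.empty((n, L), dtype=np.int64)
    for i in range(k):
        rows = np.flatnonzero(labels == i)
        for v in range(L):
            codes[rows, v] = rng.choice(4, size=rows.size, p=pwms[i, :, v])
    seeds = [
        SeedRecord(f"sim_{labels[m]}_{m}", decode_seed(codes[m])) for m in range(n)
    ]
    return SimulationTruth(
        true_pwms=pwms,
        true_lambdas=lambdas,
        labels=labels,
        seeds=seeds,
        rng_seed=int(rng_seed),
    )


def write_fixture_fasta(truth: SimulationTruth, path) -> None:
    """Write the sampled seeds as mature-length FASTA records.

    Each record is a 22-mer with the seed planted at positions 2–7 and
    uniform-random flanks, so the full pipeline including seed extraction is
    exercised. Flank bases derive deterministically from the truth's seed.
    """
    rng = np.random.default_rng([truth.rng_seed, 7])
    L = truth.L
    n_right = FIXTURE_TOTAL_LENGTH - (SEED_START - 1) - L
    with open(path, "w") as fh:
        for rec in truth.seeds:
            left = decode_seed(rng.integers(0, 4, size=SEED_START - 1))
            right = decode_seed(rng.integers(0, 4, size=n_right))
            fh.write(f">{rec.id}\n{left}{rec.seed}{right}\n")


def write_truth_json(truth: SimulationTruth, path) -> None:
    """Sidecar JSON with the generating parameters and true labels."""
    payload = {
        "schema_version": 1,
        "L": int(truth.L),
        "k": int(truth.k),
        "base_order": list(BASES),
        "lambdas": truth.true_lambdas.tolist(),
        "pwms": truth.true_pwms.tolist(),
        "rng_seed": int(truth.rng_seed),
        "labels": truth.labels.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")
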