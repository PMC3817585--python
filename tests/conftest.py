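import math

import numpy as np
import pytest

BASES = "ACGU"


# ---------------------------------------------------------------------------
# Independent brute-force oracles: plain-arithmetic implementations used to
# cross-check the vectorized/log-space library code. They deliberately share
# no code with the package.
# ---------------------------------------------------------------------------

def brute_seq_prob(seed: str, pwm) -> float:
    p = 1.0
    for v, c in enumerate(seed):
        p *= pwm[BASES.index(c)][v]
    return p


def brute_e_step(seeds, lambdas, pwms):
    rows = []
    for s in seeds:
        joint = [lam * brute_seq_prob(s, W) for lam, W in zip(lambdas, pwms)]
        tot = sum(joint)
        rows.append([j / tot for j in joint])
    return np.array(rows)


def brute_marginal_loglik(seeds, lambdas, pwms) -> float:
    total = 0.0
    for s in seeds:
        total += math.log(
            sum(lam * brute_seq_prob(s, W) for lam, W in zip(lambdas, pwms))
        )
    return total


def brute_match_score(seed: str, member_seeds) -> float:
    L = len(seed)
    n = len(member_seeds)
    num = lo = hi = 0.0
    for v in range(L):
        freqs = [sum(1 for s in member_seeds if s[v] == b) / n for b in BASES]
        info = sum(f * math.log(4 * f) for f in freqs if f > 0)
        num += info * freqs[BASES.index(seed[v])]
        lo += info * min(freqs)
        hi += info * max(freqs)
    if hi - lo == 0:
        return 0.0
    return (num - lo) / (hi - lo)


def brute_silhouette(seeds, labels):
    def dist(a, b):
        return sum(1 for x, y in zip(a, b) if x != y)

    labels = list(labels)
    groups = sorted(set(labels))
    scores = []
    for m, s in enumerate(seeds):
        own = [i for i in range(len(seeds)) if labels[i] == labels[m] and i != m]
        if not own:
            scores.append(0.0)
            continue
        alpha = sum(dist(s, seeds[i]) for i in own) / len(own)
        beta = min(
            sum(dist(s, seeds[i]) for i in range(len(seeds)) if labels[i] == g)
            / labels.count(g)
            for g in groups
            if g != labels[m]
        )
        d = max(alpha, beta)
        scores.append(0.0 if d == 0 else (beta - alpha) / d)
    return np.array(scores)


def random_instance(rng, n_max=10, k_max=3, L=4):
    """A random small mixture instance (seeds, lambdas, smoothed pwms)."""
    n = int(rng.integers(2, n_max + 1))
    k = int(rng.integers(1, k_max + 1))
    seeds = ["".join(rng.choice(list(BASES), size=L)) for _ in range(n)]
    lam = rng.dirichlet(np.ones(k))
    pwms = np.stack([rng.dirichlet(np.ones(4), size=L).T for _ in range(k)])
    pwms = (pwms + 0.01) / (pwms + 0.01).sum(axis=1, keepdims=True)
    return seeds, lam, pwms


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fasta_file(tmp_path):
    """Write FASTA text to a temp file and return its path."""

    def _write(text, name="test.fasta"):
        p = tmp_path / name
        p.write_text(text)
        return p

    return _write
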