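"""Position weight matrices (PWMs) over the RNA alphabet ``{A, C, G, U}``.

A PWM is represented as a plain ``(4, L)`` :class:`numpy.ndarray` whose rows
follow the fixed base order ``A, C, G, U`` and whose columns are seed
positions ``1..L``. Every column is a probability distribution over the four
bases. Stacks of PWMs (one per mixture component) are ``(k, 4, L)`` arrays.

All likelihood arithmetic is carried out in natural-log space.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

#: Fixed base order used everywhere, including serialization.
BASES: tuple[str, ...] = ("A", "C", "G", "U")
BASE_INDEX: dict[str, int] = {b: i for i, b in enumerate(BASES)}

LOG4 = float(np.log(4.0))


def encode_seed(seed: str) -> np.ndarray:
    """Encode a seed string into an integer vector (A=0, C=1, G=2, U=3)."""
    try:
        return np.array([BASE_INDEX[c] for c in seed], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(
            f"seed {seed!r} contains character {exc.args[0]!r} outside "
            f"the alphabet {{A, C, G, U}}"
        ) from None


def encode_seeds(seeds) -> np.ndarray:
    """Encode a collection of equal-length seeds into an ``(N, L)`` int array.

    Accepts a list of strings, a list of :class:`~mirmix.io.SeedRecord`-like
    objects (anything with a ``seed`` attribute), or an already-encoded
    integer array (returned as-is after validation).
    """
    if isinstance(seeds, np.ndarray) and seeds.ndim == 2:
        if seeds.size and (seeds.min() < 0 or seeds.max() > 3):
            raise ValueError("encoded seed array has entries outside 0..3")
        return seeds.astype(np.int64, copy=False)
    strings = [getattr(s, "seed", s) for s in seeds]
    if not strings:
        return np.empty((0, 0), dtype=np.int64)
    L = len(strings[0])
    for s in strings:
        if len(s) != L:
            raise ValueError(
                f"all seeds must share one length; got {len(s)} and {L}"
            )
    return np.vstack([encode_seed(s) for s in strings])


def decode_seed(codes: Sequence[int]) -> str:
    """Inverse of :func:`encode_seed`."""
    return "".join(BASES[int(c)] for c in codes)


def validate_pwm(pwm: np.ndarray, atol: float = 1e-9) -> np.ndarray:
    """Check that ``pwm`` is a 4×L column-stochastic matrix; return it as float."""
    pwm = np.asarray(pwm, dtype=float)
    if pwm.ndim != 2 or pwm.shape[0] != 4:
        raise ValueError(f"PWM must have shape (4, L); got {pwm.shape}")
    if np.any(pwm < 0):
        raise ValueError("PWM entries must be non-negative")
    colsums = pwm.sum(axis=0)
    if not np.allclose(colsums, 1.0, atol=atol, rtol=0.0):
        raise ValueError(f"PWM columns must sum to 1; got sums {colsums}")
    return pwm


def seq_log_likelihood(seed, pwm: np.ndarray) -> float:
    """Natural-log probability of one seed under a single PWM.

    Returns ``sum_v log W[base at v, v]``. A zero entry touched by the seed
    yields ``-inf`` (never an exception): unsmoothed matrices simply assign
    the sequence probability zero.
    """
    codes = encode_seed(seed) if isinstance(seed, str) else np.asarray(seed)
    pwm = np.asarray(pwm, dtype=float)
    if pwm.ndim != 2 or pwm.shape[0] != 4:
        raise ValueError(f"PWM must have shape (4, L); got {pwm.shape}")
    if codes.shape[0] != pwm.shape[1]:
        raise ValueError(
            f"seed length {codes.shape[0]} does not match PWM width {pwm.shape[1]}"
        )
    vals = pwm[codes, np.arange(codes.shape[0])]
    with np.errstate(divide="ignore"):
        return float(np.log(vals).sum())


def consensus(pwm: np.ndarray) -> str:
    """Per-column maximal-probability base; ties broken by base order A<C<G<U."""
    pwm = np.asarray(pwm, dtype=float)
    return decode_seed(np.argmax(pwm, axis=0))


def column_information(freqs) -> float:
    """Information content ``I(v) = sum_b f_b log(4 f_b)`` of one column.

    Uses the convention ``0 * log 0 = 0``; ranges from 0 (uniform column) to
    ``log 4`` (fully conserved column). Natural-log base.
    """
    f = np.asarray(freqs, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequencies must be non-negative")
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError(f"frequencies must sum to 1; got {f.sum()}")
    nz = f > 0
    return float((f[nz] * np.log(4.0 * f[nz])).sum())


def information_vector(freqs: np.ndarray) -> np.ndarray:
    """Vector of per-column information contents of a 4×L frequency matrix."""
    f = np.asarray(freqs, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log(4.0 * f), 0.0)
    return terms.sum(axis=0)


def window_to_pwm(window, match_weight: float = 0.7) -> np.ndarray:
    """Convert one length-L sequence window into a PWM.

    The observed base at each position receives ``match_weight``; the other
    three bases share the remainder equally.
    """
    if not 0.25 < match_weight < 1.0:
        raise ValueError("match_weight must lie in (0.25, 1)")
    codes = encode_seed(window) if isinstance(window, str) else np.asarray(window)
    L = codes.shape[0]
    pwm = np.full((4, L), (1.0 - match_weight) / 3.0)
    pwm[codes, np.arange(L)] = match_weight
    return pwm


def init_pwms(
    seeds,
    k: int,
    mode: str = "from_sequences",
    match_weight: float = 0.7,
    rng_seed: int | None = None,
    rng: np.random.Generator | None = None,
    background=None,
) -> np.ndarray:
    """Draw ``k`` initial PWMs, returned as a ``(k, 4, L)`` stack.

    ``from_sequences`` draws k length-L windows uniformly with replacement
    from a background pool (default: the input seeds themselves; pass
    ``background`` for an external pool) and spreads each window into a PWM
    via :func:`window_to_pwm`. ``dirichlet`` draws every column independently
    from a symmetric Dirichlet(1). Deterministic given the RNG seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if rng is None:
        rng = np.random.default_rng(rng_seed)
    if mode == "from_sequences":
        pool = encode_seeds(background if background is not None else seeds)
        if pool.shape[0] == 0:
            raise ValueError("from_sequences initialization needs a non-empty pool")
        idx = rng.integers(pool.shape[0], size=k)
        return np.stack([window_to_pwm(pool[i], match_weight) for i in idx])
    if mode == "dirichlet":
        L = encode_seeds(seeds).shape[1]
        return np.stack(
            [rng.dirichlet(np.ones(4), size=L).T for _ in range(k)]
        )
    raise ValueError(f"unknown init mode {mode!r}")
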