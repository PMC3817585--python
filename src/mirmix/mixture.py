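"""Mixture of position weight matrices fitted by expectation–maximization.

The generative model: each seed sequence is emitted by one of ``k`` latent
components with mixing weights ``lambda_i``; component ``i`` emits bases
independently per position according to its 4×L PWM ``W_i``, so

    P(x) = sum_i lambda_i * prod_v W_i[x_v, v].

The E-step computes the posterior responsibility of each component for each
sequence; the M-step re-estimates ``lambda`` as mean responsibilities and
each PWM from responsibility-weighted base counts (optionally pseudocount-
smoothed). An alternative ``literal`` M-step variant that re-weights the
current matrix entries instead of raw counts is kept for comparison; it does
not guarantee likelihood ascent and is not the default.

:class:`PWMMixture` wraps the engine as a scikit-learn style estimator;
:func:`fit_em` and :func:`scan_k` are the functional surface over it.
"""

from __future__ import annotations

import json
import logging
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClusterMixin

from . import pwm as _pwm
from .pwm import BASES, encode_seeds, init_pwms, validate_pwm

logger = logging.getLogger(__name__)

MODEL_SCHEMA_VERSION = 1


def _component_logliks(X: np.ndarray, pwms: np.ndarray) -> np.ndarray:
    """Per-sequence, per-component log P(x | W_i): an (N, k) matrix."""
    pwms = np.asarray(pwms, dtype=float)
    with np.errstate(divide="ignore"):
        logw = np.log(pwms)  # (k, 4, L); zero entries become -inf
    L = X.shape[1]
    return logw[:, X, np.arange(L)].sum(axis=2).T


def _posterior(X, lambdas, pwms):
    """Joint log weights, per-sequence marginal, and responsibilities."""
    logp = _component_logliks(X, pwms)
    with np.errstate(divide="ignore"):
        a = logp + np.log(np.asarray(lambdas, dtype=float))
    norm = logsumexp(a, axis=1)
    if not np.all(np.isfinite(norm)):
        bad = int(np.flatnonzero(~np.isfinite(norm))[0])
        raise ValueError(
            f"all components assign zero likelihood to sequence index {bad}; "
            "use a pseudocount > 0 to smooth the PWMs"
        )
    z = np.exp(a - norm[:, None])
    return norm, z


def e_step(seeds, lambdas, pwms) -> np.ndarray:
    """Responsibility matrix ``z[m, i] = P(component i | seed m)``.

    Computed in log space via log-sum-exp; every row sums to 1.
    """
    X = encode_seeds(seeds)
    _, z = _posterior(X, lambdas, pwms)
    return z


def marginal_loglik(seeds, lambdas, pwms) -> float:
    """Dataset marginal log-likelihood ``sum_m log sum_i lambda_i P(x_m|W_i)``."""
    X = encode_seeds(seeds)
    norm, _ = _posterior(X, lambdas, pwms)
    return float(norm.sum())


def m_step(
    seeds,
    responsibilities: np.ndarray,
    pseudocount: float = 1e-4,
    variant: str = "standard",
    pwms: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One M-step: re-estimated ``(lambdas, pwms)`` from responsibilities.

    ``standard`` maximizes the expected complete-data log-likelihood:
    responsibility-weighted base counts, smoothed by ``pseudocount`` per
    cell. ``literal`` instead scales the *current* matrix entries by the
    responsibility mass of matching bases and renormalizes per column
    (requires ``pwms``); it is not an ascent update.

    A component with zero total responsibility and zero pseudocount keeps
    its previous PWM (uniform if none was supplied) and logs a warning.
    """
    X = encode_seeds(seeds)
    z = np.asarray(responsibilities, dtype=float)
    N, L = X.shape
    k = z.shape[1]
    lambdas = z.sum(axis=0) / N

    onehot = (X[:, None, :] == np.arange(4)[None, :, None]).astype(float)
    counts = np.einsum("nk,nbl->kbl", z, onehot)  # (k, 4, L)
    totals = z.sum(axis=0)  # (k,)

    if variant == "standard":
        new = np.empty((k, 4, L))
        for i in range(k):
            denom = 4.0 * pseudocount + totals[i]
            if denom == 0.0:
                logger.warning(
                    "component %d has zero responsibility and no pseudocount; "
                    "its PWM is left unchanged",
                    i,
                )
                new[i] = pwms[i] if pwms is not None else np.full((4, L), 0.25)
            else:
                new[i] = (pseudocount + counts[i]) / denom
        return lambdas, new
    if variant == "literal":
        if pwms is None:
            raise ValueError("the literal M-step variant requires the current pwms")
        num = np.asarray(pwms, dtype=float) * counts + pseudocount
        colsums = num.sum(axis=1, keepdims=True)  # (k, 1, L)
        new = np.where(colsums > 0, num / np.where(colsums > 0, colsums, 1.0), pwms)
        if np.any(colsums == 0):
            logger.warning("literal M-step left %d degenerate columns unchanged",
                           int((colsums == 0).sum()))
        return lambdas, new
    raise ValueError(f"unknown M-step variant {variant!r}")


def run_em(
    X,
    lambdas: np.ndarray,
    pwms: np.ndarray,
    pseudocount: float = 1e-4,
    tol: float = 1e-8,
    max_iter: int = 500,
    variant: str = "standard",
):
    """Run EM to convergence from explicit initial parameters.

    Returns ``(lambdas, pwms, responsibilities, trajectory, converged,
    n_iter)`` where ``trajectory`` holds the marginal log-likelihood of the
    parameters at every iteration (index 0 is the initialization) and
    ``n_iter`` counts M-step updates performed. Convergence: relative
    log-likelihood improvement below ``tol``.
    """
    X = encode_seeds(X)
    lambdas = np.asarray(lambdas, dtype=float)
    pwms = np.asarray(pwms, dtype=float)
    trajectory: list[float] = []
    converged = False
    n_updates = 0
    while True:
        norm, z = _posterior(X, lambdas, pwms)
        ll = float(norm.sum())
        trajectory.append(ll)
        if len(trajectory) >= 2:
            prev = trajectory[-2]
            rel = (ll - prev) / abs(prev) if prev != 0.0 else np.inf
            if rel < tol:
                converged = True
                break
        if n_updates >= max_iter:
            break
        lambdas, pwms = m_step(X, z, pseudocount=pseudocount,
                               variant=variant, pwms=pwms)
        n_updates += 1
    return lambdas, pwms, z, np.array(trajectory), converged, n_updates


class PWMMixture(ClusterMixin, BaseEstimator):
    """Cluster fixed-length seed sequences with a mixture of PWMs.

    Parameters
    ----------
    n_components : int
        Number of mixture components (clusters) ``k``.
    init : {"from_sequences", "dirichlet"}
        PWM initialization: spread random data windows into matrices
        (``from_sequences``, default) or draw columns from Dirichlet(1).
    match_weight : float
        Probability given to the observed base when spreading a window into
        an initial PWM (``from_sequences`` only); in (0.25, 1).
    pseudocount : float
        Additive smoothing per PWM cell in the M-step. Zero disables
        smoothing; sequences may then receive -inf log-likelihood.
    tol : float
        Relative marginal log-likelihood improvement below which EM stops.
    max_iter : int
        Maximum number of EM iterations per restart.
    n_init : int
        Number of random restarts; the maximum-likelihood fit is kept.
    m_step_variant : {"standard", "literal"}
        M-step update rule (see :func:`m_step`).
    background : sequence of str, optional
        External pool of sequences for ``from_sequences`` initialization.
    random_state : int
        Master seed. Restart ``r`` at ``k`` components uses the NumPy seed
        sequence ``[random_state, k, r]``, so fits are reproducible end to
        end and restarts are independent.

    Attributes
    ----------
    lambdas_ : (k,) ndarray of mixing weights.
    pwms_ : (k, 4, L) ndarray of fitted PWMs.
    responsibilities_ : (N, k) ndarray of training-set posteriors.
    labels_ : (N,) ndarray of hard assignments (argmax responsibility).
    loglik_trajectory_ : (n_iter+1,) ndarray for the winning restart.
    final_loglik_ : float, marginal log-likelihood of the winning restart.
    converged_ : bool; n_iter_ : int; best_restart_ : int.
    """

    def __init__(
        self,
        n_components: int = 2,
        *,
        init: str = "from_sequences",
        match_weight: float = 0.7,
        pseudocount: float = 1e-4,
        tol: float = 1e-8,
        max_iter: int = 500,
        n_init: int = 1,
        m_step_variant: str = "standard",
        background=None,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.init = init
        self.match_weight = match_weight
        self.pseudocount = pseudocount
        self.tol = tol
        self.max_iter = max_iter
        self.n_init = n_init
        self.m_step_variant = m_step_variant
        self.background = background
        self.random_state = random_state

    def _restart_rng(self, restart: int) -> np.random.Generator:
        return np.random.default_rng(
            [int(self.random_state), int(self.n_components), int(restart)]
        )

    def fit(self, X, y=None, initial_pwms=None):
        """Fit the mixture to seed sequences.

        ``X`` may be a list of equal-length seed strings, a list of objects
        with a ``seed`` attribute, or an ``(N, L)`` integer array with bases
        encoded A=0, C=1, G=2, U=3. ``initial_pwms`` overrides the random
        initialization (single restart) when given.
        """
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")
        Xe = encode_seeds(X)
        if Xe.shape[0] == 0:
            raise ValueError("cannot fit on an empty sequence set")
        k = self.n_components
        best = None
        n_restarts = 1 if initial_pwms is not None else self.n_init
        for r in range(n_restarts):
            if initial_pwms is not None:
                pwms0 = np.stack([validate_pwm(p) for p in initial_pwms])
            else:
                pwms0 = init_pwms(
                    Xe, k, mode=self.init, match_weight=self.match_weight,
                    rng=self._restart_rng(r), background=self.background,
                )
            lambdas0 = np.full(k, 1.0 / k)
            out = run_em(
                Xe, lambdas0, pwms0,
                pseudocount=self.pseudocount, tol=self.tol,
                max_iter=self.max_iter, variant=self.m_step_variant,
            )
            if best is None or out[3][-1] > best[1][3][-1]:
                best = (r, out)
        r, (lambdas, pwms, z, traj, converged, n_iter) = best
        self.lambdas_ = lambdas
        self.pwms_ = pwms
        self.responsibilities_ = z
        self.labels_ = z.argmax(axis=1)
        self.loglik_trajectory_ = traj
        self.final_loglik_ = float(traj[-1])
        self.converged_ = converged
        self.n_iter_ = n_iter
        self.best_restart_ = r
        self.L_ = Xe.shape[1]
        self.n_features_in_ = Xe.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Posterior responsibilities of each component for new sequences."""
        return e_step(X, self.lambdas_, self.pwms_)

    def predict(self, X) -> np.ndarray:
        """Hard component assignment (argmax responsibility, ties → lowest)."""
        return self.predict_proba(X).argmax(axis=1)

    def score(self, X, y=None) -> float:
        """Mean per-sequence marginal log-likelihood."""
        Xe = encode_seeds(X)
        return marginal_loglik(Xe, self.lambdas_, self.pwms_) / Xe.shape[0]

    def consensus_strings(self) -> list[str]:
        """Consensus sequence of each fitted component."""
        return [_pwm.consensus(p) for p in self.pwms_]


def fit_em(
    seeds,
    k: int,
    init_mode: str = "from_sequences",
    pseudocount: float = 1e-4,
    tol: float = 1e-8,
    max_iter: int = 500,
    rng_seed: int = 0,
    m_step_variant: str = "standard",
    match_weight: float = 0.7,
    background=None,
) -> tuple[PWMMixture, np.ndarray]:
    """Single-restart EM fit; returns the fitted model and responsibilities."""
    model = PWMMixture(
        n_components=k, init=init_mode, match_weight=match_weight,
        pseudocount=pseudocount, tol=tol, max_iter=max_iter, n_init=1,
        m_step_variant=m_step_variant, background=background,
        random_state=rng_seed,
    ).fit(seeds)
    return model, model.responsibilities_


def scan_k(
    seeds,
    k_values: Sequence[int],
    restarts: int = 10,
    rng_seed: int = 0,
    **fit_kwargs,
):
    """Fit at each k with restarts; keep the overall maximum-likelihood model.

    Returns ``(best_model, table)`` where ``table`` is a pandas DataFrame
    with columns ``k, restart_index_of_best, best_loglik``, one row per k.
    """
    import pandas as pd

    if not k_values:
        raise ValueError("k_values must be non-empty")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    rows = []
    best_model = None
    for k in k_values:
        model = PWMMixture(
            n_components=int(k), n_init=restarts, random_state=rng_seed,
            **fit_kwargs,
        ).fit(seeds)
        rows.append(
            {"k": int(k), "restart_index_of_best": model.best_restart_,
             "best_loglik": model.final_loglik_}
        )
        if best_model is None or model.final_loglik_ > best_model.final_loglik_:
            best_model = model
    return best_model, pd.DataFrame(rows)


def assign(responsibilities: np.ndarray, ids=None, seeds=None):
    """Hard grouping from a responsibility matrix (argmax, ties → lowest index).

    Empty groups are permitted and logged. Returns a
    :class:`mirmix.scoring.Grouping`.
    """
    from .scoring import Grouping

    z = np.asarray(responsibilities, dtype=float)
    labels = z.argmax(axis=1)
    k = z.shape[1]
    if ids is None:
        ids = [f"seq_{m}" for m in range(z.shape[0])]
    empty = sorted(set(range(k)) - set(labels.tolist()))
    if empty:
        logger.info("%d of %d groups are empty: %s", len(empty), k, empty)
    if seeds is not None:
        seeds = [getattr(s, "seed", s) for s in seeds]
    return Grouping(ids=list(ids), labels=labels, k=k, seeds=seeds)


def save_model(model: PWMMixture, path) -> None:
    """Serialize a fitted model to JSON (floats at full precision)."""
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "L": int(model.L_),
        "k": int(model.n_components),
        "base_order": list(BASES),
        "lambdas": model.lambdas_.tolist(),
        "pwms": model.pwms_.tolist(),
        "rng_seed": int(model.random_state),
        "n_iter": int(model.n_iter_),
        "converged": bool(model.converged_),
        "final_loglik": float(model.final_loglik_),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def load_model(path) -> PWMMixture:
    """Reconstruct a fitted :class:`PWMMixture` from a model JSON file."""
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("base_order") != list(BASES):
        raise ValueError(f"unsupported base order {payload.get('base_order')}")
    model = PWMMixture(
        n_components=int(payload["k"]), random_state=int(payload["rng_seed"])
    )
    model.lambdas_ = np.asarray(payload["lambdas"], dtype=float)
    model.pwms_ = np.stack([validate_pwm(p) for p in payload["pwms"]])
    model.L_ = int(payload["L"])
    model.n_features_in_ = model.L_
    model.n_iter_ = int(payload["n_iter"])
    model.converged_ = bool(payload["converged"])
    model.final_loglik_ = float(payload["final_loglik"])
    return model
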