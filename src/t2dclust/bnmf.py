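"""Bayesian nonnegative matrix factorization with automatic relevance determination.

Factorizes the nonnegative doubled-trait matrix X (variants x 2*traits) as
X ~ W H, where a common relevance weight lambda_k - the variance of
half-normal priors on column k of W and row k of H, itself drawn from an
inverse-gamma hyperprior - couples each component pair.  During optimization
the relevance weights of components that do not help explain X shrink toward
zero, pruning them and yielding a data-driven rank K ("soft clustering":
variant and trait weights, with one cluster per surviving component).

The maximum-posterior objective is

    F = ||X - WH||_F^2 / (2 sigma^2)
        + sum_k (||W_.k||^2 + ||H_k.||^2) / (2 lambda_k)
        + ((N + M)/2 + a + 1) sum_k log lambda_k + sum_k b / lambda_k

minimized by alternating multiplicative updates of W and H (the standard
half-normal ARD scheme) and the closed-form stationary update of lambda.
Because the landscape is multi-modal, the factorization is run as a seeded
ensemble; the solution reported is the maximum-posterior run at the modal
effective K.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

_EPS = 1e-12  # denominator guard in multiplicative updates


@dataclass
class BnmfConfig:
    """Hyperparameters of the ARD factorization.

    ``b`` and ``sigma_sq`` default to ``None`` meaning "derive from the
    data": sigma^2 is a robust null-noise estimate, the lower quartile of
    the squared nonzero entries of X divided by the chi-square(1) 25th
    percentile (a z-score has unit sampling variance, and most variant-trait
    cells are null, so a low quantile is dominated by noise); b is set so
    the prior expected reconstruction scale K0 * E[w] E[h] matches mean(X).
    """

    k0: int = 20
    a: float = 10.0
    b: float | None = None
    tol: float = 1e-7
    max_iter: int = 100_000
    prune_eps: float = 1e-5
    sigma_sq: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k0 < 1:
            raise ValueError("k0 must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.b is None and self.a <= 2:
            raise ValueError("a must be > 2 when b is auto-derived")


@dataclass
class FactorizationResult:
    W: np.ndarray                    # variants x K0, nonnegative
    H: np.ndarray                    # K0 x doubled traits, nonnegative
    lam: np.ndarray                  # relevance weight per component
    objective_trace: np.ndarray      # negative log posterior per iteration
    effective_k: int
    converged: bool
    seed: int | None = None
    x_max: float = 1.0               # data scale anchor for pruning

    @property
    def final_objective(self) -> float:
        return float(self.objective_trace[-1])

    def surviving_components(self, prune_eps: float = 1e-5) -> np.ndarray:
        return _survivors(self.W, self.H, prune_eps, self.x_max)


@dataclass
class EnsembleResult:
    runs: pd.DataFrame               # seed, effective_k, final_objective, converged
    k_frequency: dict[int, float]
    modal_k: int
    best_run: FactorizationResult


def _survivors(W: np.ndarray, H: np.ndarray, prune_eps: float,
               x_max: float) -> np.ndarray:
    """Boolean mask of components whose W column and H row both carry weight.

    A component survives iff its max W entry and max H entry both exceed
    prune_eps times the respective global maxima, and its peak contribution
    max(W_.k) * max(H_k.) reaches prune_eps times the data scale max(X)
    (so a run where every component was regressed out reports K = 0).
    """
    w_max, h_max = W.max(), H.max()
    if w_max == 0 or h_max == 0:
        return np.zeros(W.shape[1], dtype=bool)
    w_col, h_row = W.max(axis=0), H.max(axis=1)
    return ((w_col > prune_eps * w_max) & (h_row > prune_eps * h_max)
            & (w_col * h_row > prune_eps * x_max))


def _objective(X, W, H, lam, sigma_sq, a, b) -> float:
    n, m = X.shape
    resid = X - W @ H
    fit = float(np.sum(resid * resid)) / (2.0 * sigma_sq)
    norms = np.sum(W * W, axis=0) + np.sum(H * H, axis=1)
    penalty = float(np.sum(norms / (2.0 * lam)))
    hyper = ((n + m) / 2.0 + a + 1.0) * float(np.sum(np.log(lam)))
    hyper += float(np.sum(b / lam))
    return fit + penalty + hyper


def factorize(X: np.ndarray | pd.DataFrame, cfg: BnmfConfig,
              seed: int | None = None) -> FactorizationResult:
    """Run one seeded ARD factorization of the nonnegative matrix X.

    Alternates the multiplicative updates
    ``W <- W * (X H') / (W H H' + sigma^2 W / lam)`` and
    ``H <- H * (W' X) / (W' W H + sigma^2 H / lam)`` with the closed-form
    relevance update
    ``lam_k = (||W_.k||^2/2 + ||H_k.||^2/2 + b) / ((N+M)/2 + a + 1)``,
    stopping when the relative objective change drops below ``cfg.tol``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a matrix")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite entries")
    if (X < 0).any():
        raise ValueError("X must be nonnegative")
    n, m = X.shape
    if seed is None:
        seed = cfg.seed
    k0 = cfg.k0

    if X.max() == 0.0:
        trace = np.array([0.0])
        return FactorizationResult(
            W=np.zeros((n, k0)), H=np.zeros((k0, m)),
            lam=np.full(k0, np.inf), objective_trace=trace,
            effective_k=0, converged=True, seed=seed)

    mean_x = float(X.mean())
    if cfg.sigma_sq is not None:
        sigma_sq = cfg.sigma_sq
    else:
        # robust null-noise variance: lower-quartile of squared nonzero
        # entries over the chi-square(1) 25th percentile (~0.1015); tolerates
        # up to 75% signal-carrying entries
        nonzero = X[X > 0]
        sigma_sq = float(np.quantile(nonzero * nonzero, 0.25)) / 0.1015
    sigma_sq = max(sigma_sq, _EPS)
    if cfg.b is not None:
        b = cfg.b
    else:
        # E[(WH)_ij] = k0 * (2 lam / pi) for half-normal w, h; match mean(X)
        lam_prior = np.pi * mean_x / (2.0 * k0)
        b = lam_prior * (cfg.a - 1.0)

    rng = np.random.default_rng(seed)
    scale = 2.0 * np.sqrt(mean_x / k0)
    W = rng.uniform(0.0, 1.0, size=(n, k0)) * scale
    H = rng.uniform(0.0, 1.0, size=(k0, m)) * scale
    const = (n + m) / 2.0 + cfg.a + 1.0
    lam = (0.5 * np.sum(W * W, axis=0) + 0.5 * np.sum(H * H, axis=1) + b) / const

    x_max = float(X.max())
    trace = [_objective(X, W, H, lam, sigma_sq, cfg.a, b)]
    converged = False
    for it in range(cfg.max_iter):
        W *= (X @ H.T) / (W @ (H @ H.T) + sigma_sq * W / lam + _EPS)
        H *= (W.T @ X) / ((W.T @ W) @ H + sigma_sq * H / lam[:, None] + _EPS)
        lam = (0.5 * np.sum(W * W, axis=0)
               + 0.5 * np.sum(H * H, axis=1) + b) / const
        obj = _objective(X, W, H, lam, sigma_sq, cfg.a, b)
        if not np.isfinite(obj):
            raise FloatingPointError(
                f"non-finite objective at iteration {len(trace)}")
        prev = trace[-1]
        trace.append(obj)
        # regress out components that have shrunk to irrelevance; committed
        # only when removal does not increase the objective
        if it % 25 == 24:
            dead = ~_survivors(W, H, cfg.prune_eps, x_max)
            dead &= W.max(axis=0) > 0
            if dead.any():
                W2, H2 = W.copy(), H.copy()
                W2[:, dead] = 0.0
                H2[dead, :] = 0.0
                lam2 = (0.5 * np.sum(W2 * W2, axis=0)
                        + 0.5 * np.sum(H2 * H2, axis=1) + b) / const
                obj2 = _objective(X, W2, H2, lam2, sigma_sq, cfg.a, b)
                if obj2 <= trace[-1]:
                    W, H, lam = W2, H2, lam2
                    trace.append(obj2)
                    obj = obj2
        if abs(prev - obj) <= cfg.tol * abs(prev):
            converged = True
            break

    effective_k = int(_survivors(W, H, cfg.prune_eps, x_max).sum())
    return FactorizationResult(W=W, H=H, lam=lam,
                               objective_trace=np.asarray(trace),
                               effective_k=effective_k,
                               converged=converged, seed=seed, x_max=x_max)


def run_ensemble(X: np.ndarray | pd.DataFrame, cfg: BnmfConfig,
                 n_runs: int) -> EnsembleResult:
    """Seeded ensemble of factorizations with modal-K / max-posterior selection.

    Run i uses seed ``cfg.seed + i``.  The modal effective K is the most
    frequent K over successful runs (ties broken toward the smaller K) and
    the reported solution is the run at the modal K with the smallest final
    objective, i.e. the maximum-posterior solution at the most probable K.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    results: list[FactorizationResult] = []
    rows = []
    errors = []
    for i in range(n_runs):
        seed = cfg.seed + i
        try:
            res = factorize(X, cfg, seed=seed)
        except (FloatingPointError, ValueError) as exc:  # recorded, not fatal
            errors.append((seed, str(exc)))
            continue
        results.append(res)
        rows.append({"seed": seed, "effective_k": res.effective_k,
                     "final_objective": res.final_objective,
                     "converged": res.converged})
    if not results:
        raise RuntimeError(f"all {n_runs} runs failed; first error: {errors[0]}")

    runs = pd.DataFrame(rows)
    counts = runs["effective_k"].value_counts()
    k_frequency = {int(k): float(c) / len(runs) for k, c in counts.items()}
    top = max(k_frequency.values())
    modal_k = min(k for k, f in k_frequency.items() if f == top)
    at_modal = [r for r in results if r.effective_k == modal_k]
    best_run = min(at_modal, key=lambda r: r.final_objective)
    return EnsembleResult(runs=runs, k_frequency=k_frequency,
                          modal_k=modal_k, best_run=best_run)


def component_weights(result: FactorizationResult,
                      variant_ids: list[str] | None = None,
                      trait_labels: list[str] | None = None,
                      prune_eps: float = 1e-5,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-variant (W) and per-trait (H) cluster-weight tables.

    Pruned components are dropped and the survivors ordered by descending
    total weight; trait rows keep their ``_pos``/``_neg`` direction labels.
    Returns ``(variant_weights, trait_weights)`` with columns
    ``cluster_1 .. cluster_K``.
    """
    keep = np.flatnonzero(result.surviving_components(prune_eps))
    W = result.W[:, keep]
    H = result.H[keep, :]
    order = np.argsort(-(W.sum(axis=0) + H.sum(axis=1)), kind="stable")
    W, H = W[:, order], H[order, :]
    cols = [f"cluster_{i + 1}" for i in range(len(keep))]
    if variant_ids is None:
        variant_ids = [f"v{i}" for i in range(W.shape[0])]
    if trait_labels is None:
        trait_labels = [f"t{i}" for i in range(H.shape[1])]
    variant_weights = pd.DataFrame(W, index=variant_ids, columns=cols)
    trait_weights = pd.DataFrame(H.T, index=trait_labels, columns=cols)
    return variant_weights, trait_weights
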