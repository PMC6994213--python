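"""Minimal (mu/mu_w, lambda) CMA-ES for low-dimensional box-constrained search.

Implements the standard covariance-matrix-adaptation evolution strategy
update equations (rank-one + rank-mu covariance update, cumulative step-size
adaptation) for the small (n=4) problems this package solves. Candidates are
clipped to the box before evaluation; the caller's objective handles any
further reparameterization (e.g. renormalization onto the simplex).
"""

from __future__ import annotations

from typing import Callable

import numpy as np


def cmaes_minimize(
    objective: Callable[[np.ndarray], float],
    x0: np.ndarray,
    sigma0: float,
    rng: np.random.Generator,
    max_evaluations: int,
    population_size: int | None = None,
    bounds: tuple[float, float] = (0.0, 1.0),
) -> tuple[np.ndarray, float, int]:
    """Minimize ``objective`` over the box; returns (best_x, best_f, n_evals).

    The generation stream for a given rng state is a pure prefix of any
    longer run, so the best-found value is non-increasing in
    ``max_evaluations``.
    """
    x0 = np.asarray(x0, dtype=float)
    n = x0.size
    lam = population_size or 4 + int(3 * np.log(n))
    if max_evaluations < lam:
        raise ValueError(f"max_evaluations ({max_evaluations}) < population size ({lam})")
    mu = lam // 2
    raw = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    weights = raw / raw.sum()
    mueff = 1.0 / np.sum(weights**2)

    cc = (4 + mueff / n) / (n + 4 + 2 * mueff / n)
    cs = (mueff + 2) / (n + mueff + 5)
    c1 = 2 / ((n + 1.3) ** 2 + mueff)
    cmu = min(1 - c1, 2 * (mueff - 2 + 1 / mueff) / ((n + 2) ** 2 + mueff))
    damps = 1 + 2 * max(0.0, np.sqrt((mueff - 1) / (n + 1)) - 1) + cs
    chi_n = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n**2))

    mean = x0.copy()
    sigma = float(sigma0)
    C = np.eye(n)
    ps = np.zeros(n)
    pc = np.zeros(n)

    best_x = np.clip(mean, *bounds)
    best_f = float(objective(best_x))
    evals = 1

    n_gen = (max_evaluations - 1) // lam
    for gen in range(n_gen):
        C = (C + C.T) / 2.0
        eigvals, B = np.linalg.eigh(C)
        eigvals = np.maximum(eigvals, 1e-20)
        D = np.sqrt(eigvals)

        z = rng.standard_normal((lam, n))
        y = z * D @ B.T
        xs = np.clip(mean + sigma * y, *bounds)
        fs = np.array([objective(x) for x in xs])
        evals += lam

        order = np.argsort(fs, kind="stable")
        if fs[order[0]] < best_f:
            best_f = float(fs[order[0]])
            best_x = xs[order[0]].copy()

        y_sel = y[order[:mu]]
        y_w = weights @ y_sel
        mean = mean + sigma * y_w

        inv_sqrt_y = (y_w @ B) / D @ B.T  # C^{-1/2} y_w
        ps = (1 - cs) * ps + np.sqrt(cs * (2 - cs) * mueff) * inv_sqrt_y
        hsig = (
            np.linalg.norm(ps) / np.sqrt(1 - (1 - cs) ** (2 * (gen + 1))) / chi_n
            < 1.4 + 2 / (n + 1)
        )
        pc = (1 - cc) * pc + hsig * np.sqrt(cc * (2 - cc) * mueff) * y_w
        rank_mu = (y_sel * weights[:, None]).T @ y_sel
        C = (
            (1 - c1 - cmu) * C
            + c1 * (np.outer(pc, pc) + (not hsig) * cc * (2 - cc) * C)
            + cmu * rank_mu
        )
        sigma = sigma * np.exp((cs / damps) * (np.linalg.norm(ps) / chi_n - 1))
        sigma = float(min(sigma, 1e3))

    return best_x, best_f, evals
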