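"""Aspect Bernoulli decomposition of a binary matrix, fitted by EM.

The model assumes each observed cell Y_gf is an independent Bernoulli draw
with success probability V_gf, and that the probability matrix factorises as
V = Gamma @ beta where Gamma (G x K) holds per-genome aspect weights (each
row a probability vector) and beta (K x F) holds per-aspect function
presence probabilities. A latent indicator Z_gfk attributes each cell to the
aspect that generated it; EM alternates between computing the posterior of
Z given the data (responsibilities) and re-estimating Gamma and beta.

These are the standard EM updates for this likelihood:

    E-step:  resp_gfk = Gamma_gk * beta_kf / V_gf            if Y_gf = 1
             resp_gfk = Gamma_gk * (1 - beta_kf) / (1 - V_gf) if Y_gf = 0
    M-step:  Gamma_gk <- mean_f resp_gfk
             beta_kf  <- sum_g resp_gfk * Y_gf / sum_g resp_gfk

The implementation folds both steps into four matrix products so a fit on
thousands of genomes runs in seconds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .matrix_io import BinaryMatrix

logger = logging.getLogger(__name__)

#: lower clip for probabilities entering divisions and logs; perfect fits
#: drive V to exactly 0 or 1 otherwise
EPS = 1e-12


@dataclass
class ABFit:
    """A fitted Aspect Bernoulli decomposition.

    Attributes
    ----------
    gamma : ndarray (G, K)
        Per-genome aspect weights; rows sum to 1.
    beta : ndarray (K, F)
        Per-aspect function presence probabilities in [0, 1].
    K : int
        Number of aspects.
    loglik_trace : ndarray
        Total Bernoulli log-likelihood after each EM iteration
        (non-decreasing).
    n_iter : int
        Iterations actually run by the winning restart.
    seed : int
        Derived RNG seed of the winning restart: drawing the initial
        parameters from ``numpy.random.default_rng(seed)`` and running EM
        reproduces this fit.
    """

    gamma: np.ndarray = field(repr=False)
    beta: np.ndarray = field(repr=False)
    K: int
    loglik_trace: np.ndarray = field(repr=False)
    n_iter: int
    seed: int

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.gamma.ndim != 2 or self.beta.ndim != 2:
            raise ValueError("gamma and beta must be 2-D")
        if self.gamma.shape[1] != self.K or self.beta.shape[0] != self.K:
            raise ValueError("gamma/beta shapes inconsistent with K")
        if (self.gamma < 0).any():
            raise ValueError("gamma has negative entries")
        if np.abs(self.gamma.sum(axis=1) - 1.0).max() > 1e-8:
            raise ValueError("gamma rows must sum to 1")
        if (self.beta < -1e-12).any() or (self.beta > 1 + 1e-12).any():
            raise ValueError("beta entries must lie in [0, 1]")
        self.beta = np.clip(self.beta, 0.0, 1.0)

    @property
    def G(self) -> int:
        return self.gamma.shape[0]

    @property
    def F(self) -> int:
        return self.beta.shape[1]

    @property
    def V(self) -> np.ndarray:
        """Implied presence probabilities, Gamma @ beta (G x F)."""
        return self.gamma @ self.beta


def _loglik(Y: np.ndarray, V: np.ndarray) -> float:
    Vc = np.clip(V, EPS, 1.0 - EPS)
    return float(np.sum(Y * np.log(Vc) + (1.0 - Y) * np.log1p(-Vc)))


def _em(Y: np.ndarray, gamma: np.ndarray, beta: np.ndarray,
        n_iter: int, tol: float | None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run EM from the given start; returns (gamma, beta, loglik trace).

    The trace holds the log-likelihood of the parameters after each update,
    preceded by that of the initial parameters.
    """
    Yf = Y.astype(float)
    nY = 1.0 - Yf
    F = Y.shape[1]
    trace = [_loglik(Yf, gamma @ beta)]
    for _ in range(n_iter):
        V = gamma @ beta
        Vc = np.clip(V, EPS, 1.0 - EPS)
        P1 = Yf / Vc          # Y / V        (zero where Y = 0)
        P0 = nY / (1.0 - Vc)  # (1-Y)/(1-V)  (zero where Y = 1)
        # responsibilities never materialised: the M-step needs only
        #   sum_f resp_gfk = Gamma_gk * (P1 @ beta.T + P0 @ (1-beta).T)_gk
        #   sum_g resp_gfk * Y_gf = beta_kf * (Gamma.T @ P1)_kf
        #   sum_g resp_gfk        = the above + (1-beta_kf) * (Gamma.T @ P0)_kf
        gamma_new = gamma * (P1 @ beta.T + P0 @ (1.0 - beta).T) / F
        GtP1 = gamma.T @ P1
        GtP0 = gamma.T @ P0
        num = beta * GtP1
        den = num + (1.0 - beta) * GtP0
        beta = np.divide(num, den, out=np.full_like(num, 0.5), where=den > 0)
        gamma = gamma_new
        # rows of gamma sum to 1 analytically; renormalise to kill drift
        gamma /= gamma.sum(axis=1, keepdims=True)
        ll = _loglik(Yf, gamma @ beta)
        if not np.isfinite(ll):
            raise FloatingPointError("log-likelihood became non-finite")
        trace.append(ll)
        if tol is not None and len(trace) >= 2:
            prev = trace[-2]
            if abs(ll - prev) <= tol * abs(prev):
                break
    return gamma, beta, np.asarray(trace)


def _init_params(G: int, F: int, K: int, rng: np.random.Generator
                 ) -> tuple[np.ndarray, np.ndarray]:
    # flat Dirichlet rows / mid-range beta avoid boundary starts that would
    # freeze responsibilities at 0 or 1
    gamma = rng.dirichlet(np.ones(K), size=G)
    beta = rng.uniform(0.25, 0.75, size=(K, F))
    return gamma, beta


def fit_ab(matrix: BinaryMatrix, K: int, n_iter: int = 500,
           n_restarts: int = 10, seed: int = 0, *,
           tol: float | None = 1e-10,
           init: tuple[np.ndarray, np.ndarray] | None = None,
           sort_aspects: bool = True) -> ABFit:
    """Fit the Aspect Bernoulli model, keeping the best of several restarts.

    Parameters
    ----------
    matrix : BinaryMatrix
        Observed G x F presence/absence data.
    K : int
        Number of aspects, 1 <= K <= F.
    n_iter : int
        Maximum EM iterations per restart (default 500, where the
        likelihood typically plateaus).
    n_restarts : int
        Independent random initialisations; the fit with the highest final
        log-likelihood wins (default 10).
    seed : int
        Base seed; restart i uses the seed derived from (seed, i).
    tol : float or None
        Relative log-likelihood change below which a restart stops early;
        ``None`` disables early stopping.
    init : (gamma0, beta0), optional
        Explicit starting point; forces a single restart. Intended for
        deterministic tests.
    sort_aspects : bool
        Report aspects in order of decreasing total genome weight
        sum_g Gamma_gk. Aspect labels are arbitrary under the likelihood,
        so a fixed ordering keeps output stable across runs.

    Returns
    -------
    ABFit
    """
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if K > matrix.F:
        raise ValueError(f"K={K} exceeds the number of functions F={matrix.F}")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    Y = matrix.values

    best: tuple[float, ABFit] | None = None
    n_failed = 0
    if init is not None:
        starts: list[tuple[int, tuple[np.ndarray, np.ndarray]]] = [(seed, init)]
    else:
        starts = []
        for i in range(n_restarts):
            rs = int(np.random.SeedSequence([int(seed), i]).generate_state(1)[0] % (2**31))
            starts.append((rs, _init_params(matrix.G, matrix.F, K, np.random.default_rng(rs))))
    for rs, (gamma0, beta0) in starts:
        gamma0 = np.asarray(gamma0, dtype=float)
        beta0 = np.asarray(beta0, dtype=float)
        if gamma0.shape != (matrix.G, K) or beta0.shape != (K, matrix.F):
            raise ValueError("init shapes do not match (G, K) / (K, F)")
        try:
            gamma, beta, trace = _em(Y, gamma0.copy(), beta0.copy(), n_iter, tol)
        except FloatingPointError as exc:
            n_failed += 1
            logger.warning("restart with seed %d aborted: %s", rs, exc)
            continue
        fit = ABFit(gamma=gamma, beta=beta, K=K, loglik_trace=trace,
                    n_iter=len(trace) - 1, seed=rs)
        if best is None or trace[-1] > best[0]:
            best = (float(trace[-1]), fit)
    if best is None:
        raise RuntimeError(f"all {n_restarts} restarts failed with numerical errors")
    if n_failed:
        logger.warning("%d of %d restarts aborted", n_failed, len(starts))
    fit = best[1]
    if sort_aspects and K > 1:
        order = np.argsort(-fit.gamma.sum(axis=0), kind="stable")
        fit = ABFit(gamma=fit.gamma[:, order], beta=fit.beta[order, :], K=K,
                    loglik_trace=fit.loglik_trace, n_iter=fit.n_iter, seed=fit.seed)
    return fit


def responsibilities(fit: ABFit, matrix: BinaryMatrix) -> np.ndarray:
    """Posterior aspect attributions P(Z_gfk = 1 | Y_gf) as a G x F x K array.

    For each cell the posterior is taken at the observed value of Y_gf; the
    K entries of every (g, f) slice sum to 1.
    """
    if (fit.G, fit.F) != (matrix.G, matrix.F):
        raise ValueError(
            f"fit is {fit.G}x{fit.F} but matrix is {matrix.G}x{matrix.F}")
    Y = matrix.values.astype(float)[:, :, None]
    gamma = fit.gamma[:, None, :]
    beta = fit.beta.T[None, :, :]
    V = np.clip(fit.V, EPS, 1.0 - EPS)[:, :, None]
    resp = np.where(Y == 1.0, gamma * beta / V, gamma * (1.0 - beta) / (1.0 - V))
    return resp / resp.sum(axis=2, keepdims=True)


def save_fit(fit: ABFit, directory: str | Path, *,
             genome_ids: list[str] | None = None,
             function_ids: list[str] | None = None) -> None:
    """Serialize a fit to ``gamma.tsv``, ``beta.tsv``, ``loglik.tsv`` and
    ``metadata.yaml`` inside *directory*."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    aspects = [f"aspect_{k + 1}" for k in range(fit.K)]
    g_index = genome_ids if genome_ids is not None else [str(i) for i in range(fit.G)]
    f_cols = function_ids if function_ids is not None else [str(j) for j in range(fit.F)]
    pd.DataFrame(fit.gamma, index=pd.Index(g_index, name="genome"),
                 columns=aspects).to_csv(directory / "gamma.tsv", sep="\t")
    pd.DataFrame(fit.beta, index=pd.Index(aspects, name="aspect"),
                 columns=f_cols).to_csv(directory / "beta.tsv", sep="\t")
    pd.DataFrame({"iteration": np.arange(len(fit.loglik_trace)),
                  "loglik": fit.loglik_trace}).to_csv(
        directory / "loglik.tsv", sep="\t", index=False)
    with open(directory / "metadata.yaml", "w") as fh:
        yaml.safe_dump({"K": int(fit.K), "n_iter": int(fit.n_iter),
                        "seed": int(fit.seed)}, fh)


def load_fit(directory: str | Path) -> ABFit:
    """Inverse of :func:`save_fit`."""
    directory = Path(directory)
    with open(directory / "metadata.yaml") as fh:
        meta = yaml.safe_load(fh)
    gamma = pd.read_csv(directory / "gamma.tsv", sep="\t", index_col=0).to_numpy(float)
    beta = pd.read_csv(directory / "beta.tsv", sep="\t", index_col=0).to_numpy(float)
    trace = pd.read_csv(directory / "loglik.tsv", sep="\t")["loglik"].to_numpy(float)
    gamma /= gamma.sum(axis=1, keepdims=True)  # absorb text round-off
    return ABFit(gamma=gamma, beta=beta, K=int(meta["K"]), loglik_trace=trace,
                 n_iter=int(meta["n_iter"]), seed=int(meta["seed"]))
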