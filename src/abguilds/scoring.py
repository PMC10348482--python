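"""Per-aspect function scoring and probabilistic-representative genomes.

The raw decomposition orders nothing: to turn an aspect into a candidate
guild we rank its functions by a composite score s_fk = r_fk * q_fk, where

* r_fk is the marginal attribution score — averaged over genomes, the
  posterior probability that aspect k generated the presence of function f
  (so sum_k r_fk = 1 for every function);
* q_fk is an abundance adjustment — how much more common f is among aspect
  k's probabilistic-representative genomes A_k than the average function
  there, which upweights functions actually carried by the genomes the
  aspect claims.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ab_model import ABFit, EPS
from .matrix_io import BinaryMatrix

logger = logging.getLogger(__name__)


@dataclass
class ScoreTable:
    """Scores and derived rankings for every (function, aspect) pair.

    ``r``, ``q`` and ``s`` are F x K arrays with s = r * q elementwise.
    ``ranked_functions[k]`` lists function IDs by descending s (ties broken
    by ascending function ID). ``representatives[k]`` is the disjoint
    genome set A_k.
    """

    r: np.ndarray = field(repr=False)
    q: np.ndarray = field(repr=False)
    s: np.ndarray = field(repr=False)
    function_ids: list[str]
    genome_ids: list[str]
    ranked_functions: list[list[str]]
    representatives: list[list[str]]

    @property
    def K(self) -> int:
        return self.r.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: aspect, rank, function_id, r, q, s."""
        idx = {f: i for i, f in enumerate(self.function_ids)}
        rows = []
        for k in range(self.K):
            for rank, fid in enumerate(self.ranked_functions[k], start=1):
                j = idx[fid]
                rows.append((k + 1, rank, fid, self.r[j, k], self.q[j, k], self.s[j, k]))
        return pd.DataFrame(rows, columns=["aspect", "rank", "function_id", "r", "q", "s"])

    def representatives_frame(self, fit: ABFit | None = None) -> pd.DataFrame:
        rows = []
        gidx = {g: i for i, g in enumerate(self.genome_ids)}
        for k, members in enumerate(self.representatives):
            for g in members:
                gamma = float(fit.gamma[gidx[g], k]) if fit is not None else np.nan
                rows.append((k + 1, g, gamma))
        return pd.DataFrame(rows, columns=["aspect", "genome_id", "gamma"])


def attribution_scores(fit: ABFit, matrix: BinaryMatrix, *,
                       conditional: bool = False) -> np.ndarray:
    """Marginal attribution r_fk: how much of function f's presence the
    model credits to aspect k.

    By default the posterior-given-presence expression
    Gamma_gk * beta_kf / V_gf is averaged over ALL genomes g, whether or
    not genome g actually carries f. ``conditional=True`` instead averages
    only over the genomes with Y_gf = 1 (functions absent everywhere get a
    zero column). Either way the returned F x K rows sum to 1 (where
    defined).
    """
    if (fit.G, fit.F) != (matrix.G, matrix.F):
        raise ValueError(
            f"fit is {fit.G}x{fit.F} but matrix is {matrix.G}x{matrix.F}")
    Vc = np.clip(fit.V, EPS, 1.0 - EPS)
    if not conditional:
        # r = (1/G) * beta_kf * sum_g Gamma_gk / V_gf, transposed to F x K
        r = ((fit.gamma.T @ (1.0 / Vc)) * fit.beta).T / fit.G
    else:
        Y = matrix.values.astype(float)
        counts = Y.sum(axis=0)  # genomes carrying each function
        r = ((fit.gamma.T @ (Y / Vc)) * fit.beta).T
        with np.errstate(invalid="ignore"):
            r = np.divide(r, counts[:, None], out=np.zeros_like(r),
                          where=counts[:, None] > 0)
        if (counts == 0).any():
            logger.warning(
                "%d function(s) absent from every genome have zero "
                "conditional attribution scores", int((counts == 0).sum()))
    return r


def probabilistic_representatives(fit: ABFit,
                                  genome_ids: list[str] | None = None
                                  ) -> list[list[str]]:
    """Assign each genome to at most one aspect: its argmax aspect, and
    only when that weight clears the 2/K uniformity threshold.

    The threshold excludes genomes whose aspect weights are nearly uniform
    and therefore uninformative; the resulting sets A_1..A_K are pairwise
    disjoint. Note that for K <= 2 the threshold 2/K >= 1 excludes every
    genome.
    """
    if genome_ids is None:
        genome_ids = [str(i) for i in range(fit.G)]
    if len(genome_ids) != fit.G:
        raise ValueError("genome_ids length does not match fit")
    threshold = 2.0 / fit.K
    top = np.argmax(fit.gamma, axis=1)  # ties resolve to the lowest index
    top_val = fit.gamma[np.arange(fit.G), top]
    n_tied = int((np.sum(np.isclose(fit.gamma, top_val[:, None]), axis=1) > 1).sum())
    if n_tied:
        logger.warning("%d genome(s) with tied maximal aspect weight "
                       "assigned to the lowest aspect index", n_tied)
    sets: list[list[str]] = [[] for _ in range(fit.K)]
    for g in np.flatnonzero(top_val > threshold):
        sets[top[g]].append(genome_ids[g])
    return sets


def abundance_adjustment(representatives: list[list[str]],
                         matrix: BinaryMatrix) -> np.ndarray:
    """q_fk: abundance of f within A_k relative to the mean function
    abundance within A_k.

    Empty A_k, or an A_k whose genomes carry nothing, yields an all-zero
    column (the aspect is unrepresented rather than an error).
    """
    gidx = {g: i for i, g in enumerate(matrix.genome_ids)}
    q = np.zeros((matrix.F, len(representatives)))
    for k, members in enumerate(representatives):
        if not members:
            logger.warning("aspect %d has no probabilistic representatives; "
                           "q column set to zero", k + 1)
            continue
        rows = matrix.values[[gidx[g] for g in members], :]
        counts = rows.sum(axis=0).astype(float)
        mean_abundance = counts.mean()
        if mean_abundance == 0:
            logger.warning("aspect %d representatives carry no functions; "
                           "q column set to zero", k + 1)
            continue
        q[:, k] = counts / mean_abundance
    return q


def guild_scores(r: np.ndarray, q: np.ndarray, function_ids: list[str],
                 genome_ids: list[str],
                 representatives: list[list[str]]) -> ScoreTable:
    """Combine r and q into s = r * q and rank functions per aspect."""
    r = np.asarray(r, dtype=float)
    q = np.asarray(q, dtype=float)
    if r.shape != q.shape:
        raise ValueError(f"r shape {r.shape} != q shape {q.shape}")
    if r.shape[0] != len(function_ids):
        raise ValueError("function_ids length does not match score arrays")
    s = r * q
    fids = np.asarray(function_ids)
    ranked = []
    for k in range(s.shape[1]):
        # lexsort: primary key last -> descending s, ascending ID on ties
        order = np.lexsort((fids, -s[:, k]))
        ranked.append([function_ids[j] for j in order])
    return ScoreTable(r=r, q=q, s=s, function_ids=list(function_ids),
                      genome_ids=list(genome_ids), ranked_functions=ranked,
                      representatives=representatives)


def compute_scores(fit: ABFit, matrix: BinaryMatrix, *,
                   conditional: bool = False) -> ScoreTable:
    """Full scoring pipeline: r, A_k, q, s and rankings in one call."""
    r = attribution_scores(fit, matrix, conditional=conditional)
    reps = probabilistic_representatives(fit, matrix.genome_ids)
    q = abundance_adjustment(reps, matrix)
    return guild_scores(r, q, matrix.function_ids, matrix.genome_ids, reps)
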