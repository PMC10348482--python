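"""Synthetic datasets with planted "perfect" artificial guilds.

The generator plays two roles. First, it builds a surrogate background
matrix with genuine low-rank Bernoulli structure (a ground-truth aspect
decomposition is drawn and then sampled), standing in for a real
genome x function table when one is not supplied. Second, it appends
artificial guilds: brand-new function columns that perfectly co-occur in a
chosen fraction of genomes and are absent everywhere else. Because
membership is all-or-none, recovery of these planted guilds is
unambiguous, which is what makes them usable for choosing the number of
aspects K.

Default guild parameters follow the simulation design this module
emulates: guild sizes 5, 7 or 9 functions; abundances 2, 5 or 10% of
genomes; non-overlapping insertion (a genome joins at most one guild) or,
as a sensitivity variant, independent random insertion that allows
overlaps; 100 replicates per parameter combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .matrix_io import BinaryMatrix

GUILD_SIZES = (5, 7, 9)
GUILD_ABUNDANCES = (0.02, 0.05, 0.10)

_BETA_HIGH = 0.9
_BETA_LOW = 0.05


@dataclass(frozen=True)
class ArtificialGuildSpec:
    """Parameters of one planted guild.

    n_functions new columns are appended; round(abundance * G) genomes
    carry all of them, everyone else carries none.
    """

    n_functions: int
    abundance: float
    overlap_mode: str = "non_overlapping"

    def __post_init__(self) -> None:
        if self.n_functions < 2:
            raise ValueError("a planted guild needs at least 2 functions")
        if not 0.0 < self.abundance < 1.0:
            raise ValueError("abundance must lie strictly between 0 and 1")
        if self.overlap_mode not in ("non_overlapping", "random"):
            raise ValueError(f"unknown overlap_mode {self.overlap_mode!r}")


@dataclass
class PlantedGuild:
    """Ground truth for one inserted guild."""

    guild_id: str
    function_ids: list[str]
    genome_ids: list[str]


@dataclass
class SimulatedDataset:
    """A base matrix with appended artificial guild columns plus truth."""

    matrix: BinaryMatrix = field(repr=False)
    truth: list[PlantedGuild]
    seed: int

    def truth_frame(self) -> pd.DataFrame:
        rows = [(t.guild_id, ";".join(t.function_ids), ";".join(t.genome_ids))
                for t in self.truth]
        return pd.DataFrame(rows, columns=["guild_id", "function_ids", "genome_ids"])


def _member_count(abundance: float, G: int) -> int:
    # round-half-up: 0.02 * 3840 = 76.8 -> 77
    return int(np.floor(abundance * G + 0.5))


def generate_base_matrix(G: int, F: int, n_latent: int, density: float,
                         seed: int, *, beta: np.ndarray | None = None
                         ) -> BinaryMatrix:
    """Sample a background matrix from a ground-truth aspect decomposition.

    Per-genome aspect weights are flat-Dirichlet; each aspect's presence
    probabilities are a mix of high (0.9) and low (0.05) entries, with the
    high fraction and a final rescale chosen so the expected overall cell
    density matches ``density``. Cells are then independent Bernoulli
    draws. Pass ``beta`` to override the presence-probability matrix
    entirely (it is validated, not rescaled).
    """
    if min(G, F, n_latent) < 1:
        raise ValueError("G, F and n_latent must be positive")
    if not 0.0 < density < 1.0:
        raise ValueError("density must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    if beta is None:
        n_high = int(round(F * (density - _BETA_LOW) / (_BETA_HIGH - _BETA_LOW)))
        if not 0 <= n_high <= F or not _BETA_LOW <= density <= _BETA_HIGH:
            raise ValueError(
                f"density {density} unattainable with the high "
                f"({_BETA_HIGH})/low ({_BETA_LOW}) aspect structure")
        beta = np.full((n_latent, F), _BETA_LOW)
        for k in range(n_latent):
            high = rng.choice(F, size=n_high, replace=False)
            beta[k, high] = _BETA_HIGH
        mean_beta = beta.mean()
        scale = density / mean_beta
        if scale * beta.max() > 1.0 or mean_beta == 0.0:
            raise ValueError(
                f"density {density} unattainable with the high/low aspect "
                f"structure (rescale would push probabilities above 1)")
        beta = beta * scale
    else:
        beta = np.asarray(beta, dtype=float)
        if beta.shape != (n_latent, F):
            raise ValueError(f"beta must have shape {(n_latent, F)}")
        if (beta < 0).any() or (beta > 1).any():
            raise ValueError("beta entries must lie in [0, 1]")
    gamma = rng.dirichlet(np.ones(n_latent), size=G)
    V = gamma @ beta
    Y = (rng.random((G, F)) < V).astype(np.uint8)
    genome_ids = [f"genome_{i + 1}" for i in range(G)]
    function_ids = [f"fn_{j + 1}" for j in range(F)]
    return BinaryMatrix(genome_ids, function_ids, Y)


def insert_artificial_guilds(base: BinaryMatrix,
                             specs: list[ArtificialGuildSpec],
                             seed: int) -> SimulatedDataset:
    """Append perfect planted guilds to a base matrix.

    Each guild contributes ``n_functions`` new all-zero columns set to 1
    exactly in its member genomes. Under ``non_overlapping`` mode members
    are drawn without replacement from genomes not yet claimed by another
    guild; under ``random`` mode each guild draws its members independently
    of the others, so overlaps can occur. Either way every guild gets
    exactly round(abundance * G) members.
    """
    rng = np.random.default_rng(seed)
    G = base.G
    counts = [_member_count(s.abundance, G) for s in specs]
    non_overlap_total = sum(c for c, s in zip(counts, specs)
                            if s.overlap_mode == "non_overlapping")
    if non_overlap_total > G:
        raise ValueError(
            f"non-overlapping guilds need {non_overlap_total} distinct member "
            f"genomes but the matrix has only {G}")
    available = np.ones(G, dtype=bool)
    new_cols = []
    new_ids: list[str] = []
    truth: list[PlantedGuild] = []
    for i, (spec, n_members) in enumerate(zip(specs, counts), start=1):
        if spec.overlap_mode == "non_overlapping":
            pool = np.flatnonzero(available)
            members = rng.choice(pool, size=n_members, replace=False)
            available[members] = False
        else:
            members = rng.choice(G, size=n_members, replace=False)
        members = np.sort(members)
        fids = [f"art{i}_fn{j + 1}" for j in range(spec.n_functions)]
        block = np.zeros((G, spec.n_functions), dtype=np.uint8)
        block[members, :] = 1
        new_cols.append(block)
        new_ids.extend(fids)
        truth.append(PlantedGuild(
            guild_id=f"guild_{i}", function_ids=fids,
            genome_ids=[base.genome_ids[g] for g in members]))
    values = np.hstack([base.values] + new_cols) if new_cols else base.values.copy()
    matrix = BinaryMatrix(list(base.genome_ids), list(base.function_ids) + new_ids,
                          values)
    return SimulatedDataset(matrix=matrix, truth=truth, seed=seed)


def generate_replicates(base: BinaryMatrix, specs: list[ArtificialGuildSpec],
                        n_replicates: int = 100, seed: int = 0
                        ) -> Iterator[SimulatedDataset]:
    """Yield independent planted datasets; replicate i is reproducible
    from (seed, i) alone."""
    for i in range(n_replicates):
        rep_seed = int(np.random.SeedSequence([int(seed), i]).generate_state(1)[0]
                       % (2**31))
        yield insert_artificial_guilds(base, specs, rep_seed)


def flip_noise(matrix: BinaryMatrix, p: float, seed: int) -> BinaryMatrix:
    """Flip each cell independently with probability p (annotation-error
    stress test for the fitter; the planted-guild truth is NOT updated)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("flip probability must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    flips = rng.random(matrix.values.shape) < p
    return BinaryMatrix(list(matrix.genome_ids), list(matrix.function_ids),
                        np.where(flips, 1 - matrix.values, matrix.values))
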