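"""Guild definition from ranked aspect function lists, and mapback genomes.

A guild is a prefix of an aspect's score-ranked function list together with
its mapback genomes: the genomes possessing every function in the prefix.
Two definitions are supported — a fixed number of functions (default 5), or
the largest prefix still supported by a minimum number of mapback genomes
(default 100). Mapback counts can only shrink as functions are added, which
makes the expansion curve over prefix sizes non-increasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix_io import BinaryMatrix
from .scoring import ScoreTable

logger = logging.getLogger(__name__)


@dataclass
class Guild:
    """A chosen function set F_k for one aspect plus its mapback genomes B_k.

    ``functions`` is a prefix of the aspect's score ranking, in score
    order; every genome in ``mapbacks`` has Y_gf = 1 for all f in the
    guild. ``below_threshold`` marks a minimum-mapback guild whose size-2
    prefix already failed the support threshold.
    """

    aspect: int
    functions: list[str]
    mapbacks: list[str] = field(repr=False)
    approach: str
    below_threshold: bool = False

    def __post_init__(self) -> None:
        if len(self.functions) < 2:
            raise ValueError("a guild needs at least 2 functions")
        if self.approach not in ("fixed_size", "min_mapback"):
            raise ValueError(f"unknown approach {self.approach!r}")

    @property
    def size(self) -> int:
        return len(self.functions)

    def functions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"aspect": self.aspect + 1, "approach": self.approach,
             "rank": np.arange(1, self.size + 1), "function_id": self.functions})

    def mapbacks_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"aspect": self.aspect + 1, "genome_id": self.mapbacks})


def mapback_genomes(matrix: BinaryMatrix, functions: list[str] | set[str]) -> list[str]:
    """Genomes whose rows carry a 1 at every listed function.

    An empty function set is a vacuous conjunction: every genome maps back.
    Order follows the matrix's genome order.
    """
    cols = [matrix.function_index(f) for f in functions]
    if not cols:
        return list(matrix.genome_ids)
    mask = matrix.values[:, cols].all(axis=1)
    return [g for g, m in zip(matrix.genome_ids, mask) if m]


def _check_aspect(scores: ScoreTable, aspect: int) -> None:
    if not 0 <= aspect < scores.K:
        raise IndexError(f"aspect {aspect} out of range for K={scores.K}")


def define_guild_fixed(scores: ScoreTable, matrix: BinaryMatrix, aspect: int,
                       m: int = 5) -> Guild:
    """Guild = the aspect's top-m functions by score (default m = 5)."""
    _check_aspect(scores, aspect)
    if m < 2:
        raise ValueError(f"guild size m must be >= 2, got {m}")
    if m > len(scores.function_ids):
        raise ValueError(f"m={m} exceeds the number of functions")
    functions = scores.ranked_functions[aspect][:m]
    return Guild(aspect=aspect, functions=functions,
                 mapbacks=mapback_genomes(matrix, functions),
                 approach="fixed_size")


def define_guild_min_mapback(scores: ScoreTable, matrix: BinaryMatrix,
                             aspect: int, min_genomes: int = 100) -> Guild:
    """Largest score-order prefix (size >= 2) whose mapback count still
    meets ``min_genomes``.

    Counts are non-increasing in prefix size, so the largest satisfying
    prefix is the most informative guild the support allows. If even the
    size-2 prefix falls short, that guild is returned flagged
    ``below_threshold``.
    """
    _check_aspect(scores, aspect)
    if min_genomes < 1:
        raise ValueError("min_genomes must be >= 1")
    ranking = scores.ranked_functions[aspect]
    best_size = None
    for size in range(2, len(ranking) + 1):
        if len(mapback_genomes(matrix, ranking[:size])) >= min_genomes:
            best_size = size
        else:
            break  # counts are non-increasing; no larger prefix can pass
    if best_size is None:
        functions = ranking[:2]
        logger.warning("aspect %d: size-2 prefix has fewer than %d mapback "
                       "genomes; returning it flagged below threshold",
                       aspect + 1, min_genomes)
        return Guild(aspect=aspect, functions=functions,
                     mapbacks=mapback_genomes(matrix, functions),
                     approach="min_mapback", below_threshold=True)
    functions = ranking[:best_size]
    return Guild(aspect=aspect, functions=functions,
                 mapbacks=mapback_genomes(matrix, functions),
                 approach="min_mapback")


def expansion_curve(scores: ScoreTable, matrix: BinaryMatrix, aspect: int,
                    max_size: int = 20) -> list[tuple[int, int]]:
    """Mapback genome counts as the guild prefix grows from size 2 to
    ``max_size``; the sequence is non-increasing."""
    _check_aspect(scores, aspect)
    if max_size > len(scores.function_ids):
        raise ValueError(f"max_size={max_size} exceeds the number of functions")
    ranking = scores.ranked_functions[aspect]
    curve = []
    members = np.ones(matrix.G, dtype=bool)
    members &= matrix.values[:, matrix.function_index(ranking[0])] == 1
    for size in range(2, max_size + 1):
        members &= matrix.values[:, matrix.function_index(ranking[size - 1])] == 1
        curve.append((size, int(members.sum())))
    return curve
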