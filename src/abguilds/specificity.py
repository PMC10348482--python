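"""Guild specificity via association-rule confidence.

For functions A and B, Conf(A -> B) is the fraction of genomes carrying A
that also carry B. Within a guild's mapback genomes every ordered pair has
confidence 1 by construction (mapbacks carry all guild functions); what
distinguishes a *specific* guild is that the same pairs co-occur rarely in
the outgroup — the rest of the dataset. The report therefore computes
forward and reverse confidences for every ordered guild pair in three
scopes (mapback, outgroup, all) and summarises the outgroup with its mean
and minimum off-diagonal values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd

from .guilds import Guild
from .matrix_io import BinaryMatrix

logger = logging.getLogger(__name__)


def confidence(matrix: BinaryMatrix, A: str, B: str,
               genomes: list[str] | set[str] | None = None) -> float | None:
    """Conf(A -> B) restricted to a genome subset (default: all genomes).

    Returns ``None`` ("missing") when no genome in the subset carries A:
    the ratio is undefined there and coercing it to 0 or 1 would bias the
    minimum-confidence summaries.
    """
    a = matrix.function_index(A)
    b = matrix.function_index(B)
    if genomes is None:
        rows = matrix.values
    else:
        gidx = {g: i for i, g in enumerate(matrix.genome_ids)}
        rows = matrix.values[[gidx[g] for g in genomes], :]
    n_a = int(rows[:, a].sum())
    if n_a == 0:
        return None
    n_ab = int((rows[:, a] & rows[:, b]).sum())
    return n_ab / n_a


@dataclass
class ConfidenceReport:
    """All ordered-pair confidences for one guild plus outgroup summaries.

    ``pairwise`` has columns aspect, antecedent, consequent, scope
    (mapback | outgroup | all), confidence (NaN when undefined),
    n_antecedent and n_both support counts. Summaries are taken over
    outgroup off-diagonal pairs, skipping undefined cells
    (``n_skipped_outgroup`` counts them).
    """

    guild: Guild
    pairwise: pd.DataFrame = field(repr=False)
    avg_outgroup: float | None
    min_outgroup: float | None
    n_skipped_outgroup: int


def _pair_stats(rows: np.ndarray, a: int, b: int) -> tuple[float | None, int, int]:
    n_a = int(rows[:, a].sum())
    n_ab = int((rows[:, a] & rows[:, b]).sum())
    return (None if n_a == 0 else n_ab / n_a), n_a, n_ab


def guild_confidence_report(matrix: BinaryMatrix, guild: Guild) -> ConfidenceReport:
    """Forward and reverse confidences for every pair of guild functions,
    inside the mapback genomes, in the outgroup, and overall."""
    gidx = {g: i for i, g in enumerate(matrix.genome_ids)}
    unknown = [g for g in guild.mapbacks if g not in gidx]
    if unknown:
        raise KeyError(f"mapback genome(s) not in matrix: {unknown[:3]}")
    in_mapback = np.zeros(matrix.G, dtype=bool)
    in_mapback[[gidx[g] for g in guild.mapbacks]] = True
    if not guild.mapbacks:
        logger.warning("guild for aspect %d has no mapback genomes; mapback "
                       "confidences will be missing", guild.aspect + 1)
    scopes = {"mapback": matrix.values[in_mapback],
              "outgroup": matrix.values[~in_mapback],
              "all": matrix.values}
    cols = {f: matrix.function_index(f) for f in guild.functions}
    rows_out = []
    out_vals = []
    n_skipped = 0
    for A, B in permutations(guild.functions, 2):
        for scope, rows in scopes.items():
            conf, n_a, n_ab = _pair_stats(rows, cols[A], cols[B])
            rows_out.append((guild.aspect + 1, A, B, scope,
                             np.nan if conf is None else conf, n_a, n_ab))
            if scope == "outgroup":
                if conf is None:
                    n_skipped += 1
                else:
                    out_vals.append(conf)
    pairwise = pd.DataFrame(rows_out, columns=[
        "aspect", "antecedent", "consequent", "scope", "confidence",
        "n_antecedent", "n_both"])
    avg = float(np.mean(out_vals)) if out_vals else None
    mn = float(np.min(out_vals)) if out_vals else None
    if n_skipped:
        logger.warning("guild for aspect %d: %d outgroup pair(s) had no "
                       "antecedent support and were skipped in summaries",
                       guild.aspect + 1, n_skipped)
    return ConfidenceReport(guild=guild, pairwise=pairwise, avg_outgroup=avg,
                            min_outgroup=mn, n_skipped_outgroup=n_skipped)
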