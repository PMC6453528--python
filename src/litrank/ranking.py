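"""End-to-end gene prioritization: rank every gene for a directed relation
to a target, filter direct interactors, and leave-one-out consistency
scoring against a background of existing relationships.

For ranking, one factorization of the full matrix suffices: candidate
pairs that were never observed are already zero in the preference matrix,
so their reconstructed scores are genuine predictions.  The leave-one-out
refit (zero the cell, refit, score) is reserved for judging the
consistency of relationships that *do* exist in the literature, compared
against a background sample of other existing relationships treated the
same way.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .als import ALSConfig, ALSResults, fit_implicit_als
from .relations import InteractionMatrix

__all__ = [
    "RankedGene",
    "RankedGeneList",
    "rank_relation",
    "rank_from_results",
    "remove_direct",
    "consistency_score",
]


@dataclass(frozen=True)
class RankedGene:
    """One candidate gene with its predicted-relation score and rank."""

    symbol: str
    score: float
    known: bool  # nonzero in the observed matrix for the target pair
    rank: int  # 1 = best
    percentile: float  # 100 * rank / n_ranked, in (0, 100]


@dataclass
class RankedGeneList:
    """All candidate genes ordered by predicted score for one target.

    Entries are sorted by descending score with ties broken by gene
    symbol; the target itself is excluded.
    """

    target: str
    direction: str  # "downstream" | "upstream"
    entries: list[RankedGene]

    @property
    def n_ranked(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, i: int) -> RankedGene:
        return self.entries[i]

    def rank_of(self, symbol: str) -> int:
        for e in self.entries:
            if e.symbol == symbol:
                return e.rank
        raise KeyError(symbol)

    def symbols(self) -> list[str]:
        return [e.symbol for e in self.entries]

    def known_only(self) -> list[RankedGene]:
        return [e for e in self.entries if e.known]

    def novel_only(self) -> "RankedGeneList":
        """Re-ranked list with known (directly observed) genes dropped."""
        return _rebuild(self, [e for e in self.entries if not e.known])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": [e.symbol for e in self.entries],
                "score": [e.score for e in self.entries],
                "known": [int(e.known) for e in self.entries],
                "rank": [e.rank for e in self.entries],
                "percentile": [e.percentile for e in self.entries],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _rebuild(ranked: RankedGeneList, kept: list[RankedGene]) -> RankedGeneList:
    n = len(kept)
    entries = [
        replace(e, rank=i + 1, percentile=100.0 * (i + 1) / n)
        for i, e in enumerate(kept)
    ]
    return RankedGeneList(ranked.target, ranked.direction, entries)


def rank_from_results(
    results: ALSResults, target: str, direction: str = "downstream"
) -> RankedGeneList:
    """Rank all genes but the target from an already-fitted factorization."""
    if direction not in ("downstream", "upstream"):
        raise ValueError(f"direction must be downstream or upstream, got {direction!r}")
    matrix = results.matrix
    idx = matrix.index
    t = idx.row(target)
    if direction == "downstream":
        scores = results.score_downstream(target)
        observed = matrix.counts.getrow(t).toarray().ravel()
    else:
        scores = results.score_upstream(target)
        observed = matrix.counts.getcol(t).toarray().ravel()

    order = sorted(
        (g for g in range(len(idx)) if g != t),
        key=lambda g: (-scores[g], idx.symbols[g]),
    )
    n = len(order)
    entries = [
        RankedGene(
            symbol=idx.symbols[g],
            score=float(scores[g]),
            known=observed[g] > 0,
            rank=r + 1,
            percentile=100.0 * (r + 1) / n,
        )
        for r, g in enumerate(order)
    ]
    return RankedGeneList(target, direction, entries)


def rank_relation(
    matrix: InteractionMatrix,
    target: str,
    direction: str = "downstream",
    config: ALSConfig | None = None,
) -> RankedGeneList:
    """Fit one factorization and rank all other genes for the target.

    ``known`` flags genes whose directed pair with the target is already
    nonzero in the observed matrix; they are ranked in place (use
    :meth:`RankedGeneList.novel_only` to drop them).
    """
    config = config or ALSConfig()
    matrix.index.row(target)  # raise early on unknown symbol
    results = fit_implicit_als(matrix, config)
    return rank_from_results(results, target, direction)


def remove_direct(ranked: RankedGeneList, matrix: InteractionMatrix) -> RankedGeneList:
    """Drop direct interactors of the target, in either orientation.

    Direct relationships tend to be transient proximal effects already
    known to the literature; removing them after ranking leaves the
    indirect, hypothesis-generating candidates.  Survivors are re-ranked
    1..m in their original order and percentiles recomputed.
    """
    direct = matrix.downstream_set(ranked.target) | matrix.upstream_set(ranked.target)
    return _rebuild(ranked, [e for e in ranked.entries if e.symbol not in direct])


def _refit_score(
    matrix: InteractionMatrix, i: int, j: int, config: ALSConfig
) -> float:
    """Zero the (i, j) cell (if nonzero), refit, and score that cell."""
    counts = matrix.counts
    if counts[i, j] != 0:
        counts = counts.copy().tolil()
        counts[i, j] = 0
        counts = counts.tocsr()
        counts.eliminate_zeros()
        matrix = InteractionMatrix(counts, matrix.index)
    results = fit_implicit_als(matrix, config)
    return float(results.W[i] @ results.H[:, j])


def consistency_score(
    matrix: InteractionMatrix,
    agent: str,
    theme: str,
    config: ALSConfig | None = None,
    background_size: int = 200,
    seed: int = 0,
) -> float:
    """Leave-one-out percentile of a relationship against a background.

    The (agent, theme) cell is zeroed (a no-op if already zero), the
    factorization refitted, and the reconstructed score recorded.  The
    same zero-refit-score procedure is applied to ``background_size``
    existing relationships sampled uniformly from the nonzero cells, and
    the focal score's percentile within that background sample (fraction
    of background scores it meets or beats, in percent) is returned.
    """
    config = config or ALSConfig()
    idx = matrix.index
    i, j = idx.row(agent), idx.col(theme)

    coo = matrix.counts.tocoo()
    pool = [(r, c) for r, c in zip(coo.row, coo.col) if (r, c) != (i, j)]
    if background_size > len(pool):
        raise ValueError(
            f"background_size {background_size} exceeds the {len(pool)} "
            "available nonzero relationships"
        )
    rng = np.random.default_rng(seed)
    chosen = [pool[t] for t in rng.choice(len(pool), background_size, replace=False)]

    focal = _refit_score(matrix, i, j, config)
    background = np.array([_refit_score(matrix, r, c, config) for r, c in chosen])
    return 100.0 * float(np.mean(focal >= background))
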