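"""Evaluation of a gene ranking against an expert gold-standard list.

The headline metric is the rank-sum ROC AUC: the probability that a
uniformly drawn gold (positive) gene outranks a uniformly drawn
non-gold (negative) gene, tied pairs counted half — equivalently the
trapezoidal area under the stepwise ROC curve.  Top-percentile recall
counts how many gold genes fall inside a leading percentile band, and
the co-occurrence baseline ranks genes by raw abstract co-occurrence
counts with competition ranking for ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GoldSet",
    "EvalReport",
    "roc_auc",
    "roc_auc_from_scores",
    "roc_points",
    "recall_at_percentile",
    "cooccurrence_rank",
    "percentile",
    "format_percentile",
    "evaluate_ranking",
    "plot_roc",
]


@dataclass
class GoldSet:
    """An expert gene list used as the positive class."""

    symbols: set[str]

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError("gold set must be nonempty")

    @classmethod
    def from_file(cls, path) -> "GoldSet":
        with open(path) as fh:
            symbols = {line.strip() for line in fh if line.strip()}
        return cls(symbols)

    def resolve(self, universe: list[str] | set[str]) -> set[str]:
        """Symbols present in the ranked universe; report the rest.

        Unresolvable gold genes are excluded from both numerator and
        denominator of any downstream metric, with a warning — silently
        counting them as missed would deflate AUC unverifiably.
        """
        universe = set(universe)
        resolved = self.symbols & universe
        missing = self.symbols - universe
        if missing:
            logger.warning(
                "%d gold gene(s) not in the ranked universe: %s",
                len(missing),
                ", ".join(sorted(missing)),
            )
        return resolved


def roc_auc(ranks_of_positives, n_total: int) -> float:
    """Rank-sum AUC from the positive genes' ranks in a total ordering.

    ``ranks_of_positives`` are 1-based positions (1 = best) among
    ``n_total`` ranked items; positions must be distinct.  Returns the
    probability that a random positive outranks a random negative:
    AUC = (sum of (n_total - r_i) - C(P, 2)) / (P * N).
    """
    ranks = np.asarray(sorted(ranks_of_positives), dtype=np.int64)
    p = len(ranks)
    if p == 0:
        raise ValueError("need at least one positive rank")
    if n_total < p:
        raise ValueError("n_total smaller than the number of positives")
    if ranks[0] < 1 or ranks[-1] > n_total:
        raise ValueError("ranks must lie in 1..n_total")
    if len(np.unique(ranks)) != p:
        raise ValueError("positive ranks must be distinct; for tied "
                         "orderings evaluate from scores instead")
    n_neg = n_total - p
    if n_neg == 0:
        raise ValueError("no negatives to compare against")
    # items ranked worse than positive i: n_total - r_i, of which
    # (p - 1 - i) are positives (ranks sorted ascending)
    wins = np.sum(n_total - ranks) - p * (p - 1) // 2
    return float(wins) / (p * n_neg)


def roc_auc_from_scores(scores, labels) -> float:
    """Midrank (tie-aware) AUC from raw scores and binary labels.

    Equivalent to the Mann-Whitney U statistic normalized by the number
    of positive-negative pairs, ties counted half; higher score = better.
    """
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    p = int(labels.sum())
    n_neg = int((~labels).sum())
    if p == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative")
    r = rankdata(scores)  # ascending, average ties
    u = float(r[labels].sum()) - p * (p + 1) / 2.0
    return u / (p * n_neg)


def roc_points(ranks_of_positives, n_total: int) -> list[tuple[float, float]]:
    """Stepwise ROC curve (FPR, TPR) points from (0, 0) to (1, 1)."""
    ranks = sorted(ranks_of_positives)
    p = len(ranks)
    n_neg = n_total - p
    pts = [(0.0, 0.0)]
    tp = fp = 0
    rank_set = set(ranks)
    for r in range(1, n_total + 1):
        if r in rank_set:
            tp += 1
        else:
            fp += 1
        pts.append((fp / n_neg, tp / p))
    return pts


def recall_at_percentile(
    ranks_of_positives,
    n_total: int,
    threshold_percent: float,
    rounding: str = "nearest",
) -> int:
    """Count of positives in the leading percentile band.

    ``nearest`` counts positives whose percentile 100*rank/n_total,
    rounded to the nearest integer percent, is <= threshold (so a gene at
    20.41% counts as "top 20%"); ``strict`` uses rank <=
    floor(threshold * n_total / 100).
    """
    if not 0 < threshold_percent <= 100:
        raise ValueError("threshold must be in (0, 100]")
    ranks = np.asarray(list(ranks_of_positives), dtype=np.int64)
    if rounding == "nearest":
        pct = np.rint(100.0 * ranks / n_total)
        return int(np.sum(pct <= threshold_percent))
    if rounding == "strict":
        return int(np.sum(ranks <= np.floor(threshold_percent * n_total / 100.0)))
    raise ValueError(f"rounding must be 'nearest' or 'strict', got {rounding!r}")


def cooccurrence_rank(counts: dict[str, int]) -> list[tuple[str, int, int]]:
    """Rank genes by descending co-occurrence count, competition style.

    Tied genes share the rank 1 + (number of genes with a strictly
    greater count).  Returns (gene, count, rank) sorted by rank then
    symbol.
    """
    if not counts:
        raise ValueError("counts must be nonempty")
    values = np.array(list(counts.values()))
    out = []
    for gene, c in counts.items():
        rank = 1 + int(np.sum(values > c))
        out.append((gene, c, rank))
    return sorted(out, key=lambda t: (t[2], t[0]))


def percentile(rank: int, n_total: int) -> float:
    """Percentile position 100 * rank / n_total of a 1-based rank."""
    if not 1 <= rank <= n_total:
        raise ValueError(f"rank {rank} outside 1..{n_total}")
    return 100.0 * rank / n_total


def format_percentile(rank: int, n_total: int) -> str:
    """Display form: nearest integer percent, or two decimals below 1%.

    A rank of 3 among 13,595 displays as "0.02%" (integer rounding would
    collapse it to 0%); a rank of 2,240 displays as "16%".
    """
    p = percentile(rank, n_total)
    if round(p) < 1:
        return f"{p:.2f}%"
    return f"{round(p):.0f}%"


@dataclass
class EvalReport:
    """ROC evaluation of one ranking against one gold set."""

    auc: float
    roc_points: list[tuple[float, float]]
    recall_at: dict[float, int]
    n_ranked: int
    n_positives: int
    positive_ranks: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "n_ranked": self.n_ranked,
            "n_positives": self.n_positives,
            "recall_at": {str(k): v for k, v in self.recall_at.items()},
            "positive_ranks": self.positive_ranks,
        }


def evaluate_ranking(
    ranked, gold: GoldSet, thresholds=(5.0, 20.0), rounding: str = "nearest"
) -> EvalReport:
    """Score a :class:`~litrank.ranking.RankedGeneList` against a gold set."""
    universe = ranked.symbols()
    resolved = gold.resolve(universe)
    if not resolved:
        raise ValueError("no gold gene resolves against the ranked universe")
    pos_ranks = {e.symbol: e.rank for e in ranked if e.symbol in resolved}
    ranks = list(pos_ranks.values())
    n = ranked.n_ranked
    return EvalReport(
        auc=roc_auc(ranks, n),
        roc_points=roc_points(ranks, n),
        recall_at={t: recall_at_percentile(ranks, n, t, rounding) for t in thresholds},
        n_ranked=n,
        n_positives=len(ranks),
        positive_ranks=dict(sorted(pos_ranks.items(), key=lambda kv: kv[1])),
    )


def plot_roc(report: EvalReport, path=None, ax=None):
    """Plot the ROC curve; writes ``path`` if given, returns the axes."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    fpr, tpr = zip(*report.roc_points)
    ax.plot(fpr, tpr, drawstyle="steps-post", label=f"AUC = {report.auc:.2f}")
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
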