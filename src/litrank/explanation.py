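"""Similar-row explanations for predicted gene relationships.

A factorization score is trusted more readily when it can be traced to
an analogy: the candidate gene connects to much the same partners as
some other gene that *does* carry the predicted relation.  For a query
gene, every other gene is compared via the 2x2 contingency of the
partner universe — is a partner connected to the query? to the other
gene? — scored with the one-degree-of-freedom chi-squared statistic
(no continuity correction by default) and its upper-tail p-value.
"connections" here means the orientation-collapsed union of in- and
out-edges in the binary view, so each gene has a single total degree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy import stats

from .als import ALSResults
from .relations import InteractionMatrix

__all__ = ["SimilarityExplanation", "ExplanationBundle", "similar_rows", "explain_prediction"]


@dataclass(frozen=True)
class SimilarityExplanation:
    """One similar-gene record justifying a prediction.

    ``shared_connections`` is the overlap of the two genes' partner
    sets over the partner universe (all genes except the pair itself);
    ``p_value`` is the chi-squared upper tail of the independence test
    on the 2x2 partner table.
    """

    query_gene: str
    similar_gene: str
    shared_connections: int
    similar_total: int
    query_total: int
    chi2_statistic: float
    p_value: float
    carries_connection: bool = False


def _undirected_binary(matrix: InteractionMatrix) -> sp.csr_matrix:
    a = matrix.counts + matrix.counts.T
    a = (a > 0).astype(np.float64)
    a.setdiag(0)
    a.eliminate_zeros()
    return sp.csr_matrix(a)


def chi2_2x2(a: float, b: float, c: float, d: float, yates: bool = False) -> tuple[float, float]:
    """Chi-squared statistic and upper-tail p for one 2x2 table.

    Returns (0.0, 1.0) for degenerate tables with an empty margin.
    """
    n = a + b + c + d
    m1, m2, m3, m4 = a + b, c + d, a + c, b + d
    denom = m1 * m2 * m3 * m4
    if denom == 0 or n == 0:
        return 0.0, 1.0
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2.0, 0.0)
    chi2 = n * diff**2 / denom
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def similar_rows(
    matrix: InteractionMatrix,
    query: str,
    top_n: int = 10,
    *,
    target: str | None = None,
    direction: str = "downstream",
    yates: bool = False,
) -> list[SimilarityExplanation]:
    """Genes whose connection pattern most resembles the query's.

    For every other gene g the 2x2 table over the partner universe
    (genes other than the query and g) is::

                          partner ~ g   partner !~ g
        partner ~ query        a             b
        partner !~ query       c             d

    Results are the ``top_n`` genes ascending by p-value (ties broken by
    more shared connections, then symbol).  If ``target`` is given,
    ``carries_connection`` flags genes that themselves carry the directed
    relation being explained (target -> gene for downstream, gene ->
    target for upstream).
    """
    idx = matrix.index
    q = idx.row(query)
    A = _undirected_binary(matrix)
    deg = np.asarray(A.sum(axis=1)).ravel()
    if deg[q] == 0:
        raise ValueError(f"query gene {query!r} has no connections")

    n = len(idx)
    aq = A.getrow(q)
    # partners in N(query) & N(g); diagonal of A is zero so the pair
    # itself never counts as a partner
    shared = np.asarray((aq @ A).todense()).ravel()
    edge_qg = np.asarray(aq.todense()).ravel()
    q_tot = deg[q] - edge_qg  # |N(query) \ {g}|
    g_tot = deg - edge_qg  # |N(g) \ {query}|
    universe = n - 2

    a = shared
    b = q_tot - shared
    c = g_tot - shared
    d = universe - q_tot - g_tot + shared

    if target is not None:
        t = idx.row(target)
        if direction == "downstream":
            carries = np.asarray(matrix.counts.getrow(t).todense()).ravel() > 0
        elif direction == "upstream":
            carries = np.asarray(matrix.counts.getcol(t).todense()).ravel() > 0
        else:
            raise ValueError(f"direction must be downstream or upstream, got {direction!r}")
    else:
        carries = np.zeros(n, dtype=bool)

    out = []
    depleted: dict[str, bool] = {}
    for g in range(n):
        if g == q:
            continue
        chi2, p = chi2_2x2(a[g], b[g], c[g], d[g], yates=yates)
        # overlap below its independence expectation is dissimilarity; the
        # p-value is kept as-is (plain chi-squared upper tail) but such
        # genes sort after every enriched one
        expected = q_tot[g] * g_tot[g] / universe if universe else 0.0
        depleted[idx.symbols[g]] = a[g] < expected
        out.append(
            SimilarityExplanation(
                query_gene=query,
                similar_gene=idx.symbols[g],
                shared_connections=int(a[g]),
                similar_total=int(g_tot[g]),
                query_total=int(q_tot[g]),
                chi2_statistic=chi2,
                p_value=p,
                carries_connection=bool(carries[g]),
            )
        )
    out.sort(
        key=lambda e: (depleted[e.similar_gene], e.p_value, -e.shared_connections, e.similar_gene)
    )
    return out[:top_n]


@dataclass
class ExplanationBundle:
    """Everything supporting one predicted relationship."""

    target: str
    candidate: str
    direction: str
    predicted_score: float
    similar: list[SimilarityExplanation]  # only genes carrying the relation
    direct_edges: list[tuple[str, str, int]]  # (agent, theme, count)


def explain_prediction(
    matrix: InteractionMatrix,
    results: ALSResults,
    target: str,
    candidate: str,
    direction: str = "downstream",
    top_n: int = 10,
) -> ExplanationBundle:
    """Explain why ``candidate`` scores for a directed relation to ``target``.

    The bundle holds (a) the factorization score of the pair, (b) the
    candidate's most similar genes filtered to those that themselves
    carry the predicted relation, and (c) any direct observed edges
    between target and candidate.
    """
    if direction == "downstream":
        score = results.score(target, candidate)
    else:
        score = results.score(candidate, target)

    sims = similar_rows(
        matrix, candidate, top_n=matrix.n_genes, target=target, direction=direction
    )
    carriers = [s for s in sims if s.carries_connection][:top_n]

    direct = []
    for agent, theme in ((target, candidate), (candidate, target)):
        c = matrix.count(agent, theme)
        if c > 0:
            direct.append((agent, theme, c))
    return ExplanationBundle(target, candidate, direction, score, carriers, direct)
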