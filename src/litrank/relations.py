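"""Relation triples, the relation catalog, and the gene-gene interaction matrix.

The raw material of literature-network inference is a set of directed
assertions mined from scientific text: *agent* gene → *relation* → *theme*
gene, backed by some number of supporting articles.  Relations come from a
catalog of canonical interaction types ("Regulation Positive",
"Phosphorylation", ...); some, like "Binding", carry no direction and count
toward both orientations.  Aggregating the triples over a common gene
universe produces a sparse agent × theme count matrix whose binary view is
the preference matrix consumed by the factorization engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "RelationCatalogEntry",
    "RelationCatalog",
    "RelationTriple",
    "GeneIndex",
    "InteractionMatrix",
    "TripleParseError",
    "UnknownGeneError",
    "default_catalog",
    "read_triples",
    "write_triples",
    "build_matrix",
]


class TripleParseError(ValueError):
    """Raised when an edge-list file cannot be parsed at all."""


class UnknownGeneError(KeyError):
    """Raised when a gene symbol is not present in a matrix index."""

    def __init__(self, symbol: str):
        super().__init__(symbol)
        self.symbol = symbol

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"gene symbol {self.symbol!r} is not in the matrix index"


@dataclass(frozen=True)
class RelationCatalogEntry:
    """One canonical interaction type.

    Parameters
    ----------
    canonical_name
        Canonical form of the relation, e.g. ``"Regulation Negative"``.
    trigger_phrases
        Lowercase surface phrases that map to this canonical form
        ("inhibit", "inhibits", ...).  Informational here; text extraction
        is out of scope, but the catalog keeps the mapping for provenance.
    directional
        Whether the relation has a causal agent and an affected theme.
        Binding-type relations are symmetric and contribute to both
        orientations of the matrix.
    """

    canonical_name: str
    trigger_phrases: frozenset[str] = frozenset()
    directional: bool = True

    def __post_init__(self) -> None:
        if not self.canonical_name:
            raise ValueError("canonical_name must be nonempty")
        for phrase in self.trigger_phrases:
            if not phrase or phrase != phrase.lower():
                raise ValueError(
                    f"trigger phrase {phrase!r} must be nonempty lowercase"
                )


class RelationCatalog:
    """A lookup of canonical relation names to their catalog entries."""

    def __init__(self, entries: list[RelationCatalogEntry]):
        names = [e.canonical_name for e in entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate canonical_name in catalog")
        self._entries = {e.canonical_name: e for e in entries}

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __getitem__(self, name: str) -> RelationCatalogEntry:
        return self._entries[name]

    def __iter__(self):
        return iter(self._entries.values())

    def is_directional(self, name: str) -> bool:
        """Direction of an unknown relation defaults to directional."""
        entry = self._entries.get(name)
        return True if entry is None else entry.directional


def default_catalog() -> RelationCatalog:
    """A small catalog of common gene-gene interaction types.

    Binding is the canonical non-directional relation; everything else has
    a causal agent.  "Association" is the fallback for unmapped relation
    names in input files.
    """
    return RelationCatalog(
        [
            RelationCatalogEntry("Regulation Positive", frozenset({"activates", "upregulates", "induces"})),
            RelationCatalogEntry("Regulation Negative", frozenset({"inhibits", "downregulates", "represses"})),
            RelationCatalogEntry("Regulation", frozenset({"regulates", "modulates"})),
            RelationCatalogEntry("Phosphorylation", frozenset({"phosphorylates"})),
            RelationCatalogEntry("Expression", frozenset({"expresses"})),
            RelationCatalogEntry("Binding", frozenset({"binds", "interacts with"}), directional=False),
            RelationCatalogEntry("Association", frozenset()),
        ]
    )


@dataclass(frozen=True, order=True)
class RelationTriple:
    """One directed literature assertion agent → theme.

    ``article_count`` is the number of distinct supporting documents; it
    must be at least 1.  Self-loops (agent == theme) are permitted but
    flagged via :attr:`is_self_loop`.
    """

    agent: str
    relation: str
    theme: str
    article_count: int

    def __post_init__(self) -> None:
        if not self.agent or not self.theme:
            raise ValueError("agent and theme must be nonempty gene symbols")
        if self.article_count < 1:
            raise ValueError(
                f"article_count must be >= 1, got {self.article_count}"
            )

    @property
    def is_self_loop(self) -> bool:
        return self.agent == self.theme


@dataclass
class GeneIndex:
    """Bijective gene-symbol ↔ ordinal maps for matrix rows and columns.

    Rows (agents) and columns (themes) share one gene universe: any gene
    observed anywhere in the triples can act as agent or theme, so the
    matrix is square and every gene can be scored downstream of any other.
    """

    symbols: list[str]
    symbol_to_row: dict[str, int] = field(init=False)
    symbol_to_col: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("gene symbols must be unique")
        mapping = {s: i for i, s in enumerate(self.symbols)}
        self.symbol_to_row = mapping
        self.symbol_to_col = dict(mapping)

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbol_to_row

    def row(self, symbol: str) -> int:
        try:
            return self.symbol_to_row[symbol]
        except KeyError:
            raise UnknownGeneError(symbol) from None

    col = row  # square convention: same universe on both axes


class InteractionMatrix:
    """Sparse agent × theme article-count matrix over a gene universe.

    ``counts[i, j]`` sums the article counts of every triple asserting
    agent *i* → theme *j* (non-directional relations having been expanded
    to both orientations).  The binary view ``binary[i, j] = 1 iff
    counts[i, j] > 0`` is the preference matrix the factorization models.
    """

    def __init__(self, counts: sp.spmatrix, index: GeneIndex):
        counts = sp.csr_matrix(counts)
        if counts.shape != (len(index), len(index)):
            raise ValueError("counts shape does not match gene index")
        if counts.nnz and counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        counts.eliminate_zeros()
        self.counts: sp.csr_matrix = counts
        self.index = index

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def n_genes(self) -> int:
        return len(self.index)

    @property
    def binary(self) -> sp.csr_matrix:
        b = self.counts.copy()
        b.data = np.ones_like(b.data)
        return b

    def count(self, agent: str, theme: str) -> int:
        return int(self.counts[self.index.row(agent), self.index.col(theme)])

    def downstream_set(self, target: str) -> set[str]:
        """Genes with a direct literature edge *from* the target.

        Themes j with counts[target, j] > 0, the target itself excluded.
        """
        i = self.index.row(target)
        cols = self.counts.getrow(i).indices
        return {self.index.symbols[j] for j in cols if j != i}

    def upstream_set(self, target: str) -> set[str]:
        """Genes with a direct literature edge *to* the target."""
        j = self.index.col(target)
        rows = sp.csc_matrix(self.counts).getcol(j).indices
        return {self.index.symbols[i] for i in rows if i != j}

    def neighbors(self, gene: str) -> set[str]:
        """Orientation-collapsed neighbor set (in- and out-edges)."""
        return self.downstream_set(gene) | self.upstream_set(gene)

    def to_coordinate_frame(self) -> pd.DataFrame:
        """Coordinate-text export: (agent symbol, theme symbol, count)."""
        coo = self.counts.tocoo()
        syms = np.asarray(self.index.symbols, dtype=object)
        df = pd.DataFrame(
            {"agent": syms[coo.row], "theme": syms[coo.col], "count": coo.data}
        )
        return df.sort_values(["agent", "theme"], ignore_index=True)

    def write_coordinate(self, path) -> None:
        self.to_coordinate_frame().to_csv(path, index=False)


def read_triples(
    path,
    catalog: RelationCatalog | None = None,
    *,
    agent_col: str = "agent",
    relation_col: str = "relation",
    theme_col: str = "theme",
    count_col: str = "count",
    default_relation: str = "Association",
) -> list[RelationTriple]:
    """Parse an edge-list CSV of directed relation triples.

    The file must carry a header naming at least the agent, theme and
    count columns (names configurable to tolerate whatever schema the
    source network ships with); the relation column is optional, and
    relation names absent from the catalog map to ``default_relation``.
    Malformed rows (empty symbols, non-positive or non-integer counts) are
    rejected individually and reported with their line numbers.
    """
    catalog = catalog or default_catalog()
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - malformed CSV edge case
        raise TripleParseError(f"cannot parse {path}: {exc}") from exc

    missing = [c for c in (agent_col, theme_col, count_col) if c not in df.columns]
    if missing:
        raise TripleParseError(
            f"{path}: missing mandatory column(s) {missing}; found {list(df.columns)}"
        )
    has_relation = relation_col in df.columns

    triples: list[RelationTriple] = []
    bad_rows: list[tuple[int, str]] = []
    for pos, row in enumerate(df.itertuples(index=False)):
        lineno = pos + 2  # 1-based, after the header line
        rec = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        agent = str(rec[agent_col]).strip()
        theme = str(rec[theme_col]).strip()
        raw_count = str(rec[count_col]).strip()
        relation = str(rec[relation_col]).strip() if has_relation else ""
        if relation not in catalog:
            relation = default_relation
        try:
            count = int(raw_count)
        except ValueError:
            bad_rows.append((lineno, f"non-integer count {raw_count!r}"))
            continue
        try:
            triples.append(RelationTriple(agent, relation, theme, count))
        except ValueError as exc:
            bad_rows.append((lineno, str(exc)))

    if bad_rows:
        detail = "; ".join(f"line {ln}: {msg}" for ln, msg in bad_rows[:10])
        logger.warning(
            "%s: rejected %d malformed row(s) (%s)", path, len(bad_rows), detail
        )
    if not triples:
        logger.warning("%s: no valid triples parsed", path)
    return triples


def write_triples(triples: list[RelationTriple], path) -> None:
    """Write triples in the same CSV dialect, canonically sorted.

    Counts for identical (agent, relation, theme) assertions are
    aggregated, so read → write → read round-trips the triple multiset.
    """
    agg: dict[tuple[str, str, str], int] = {}
    for t in triples:
        key = (t.agent, t.relation, t.theme)
        agg[key] = agg.get(key, 0) + t.article_count
    df = pd.DataFrame(
        [(a, r, th, c) for (a, r, th), c in sorted(agg.items())],
        columns=["agent", "relation", "theme", "count"],
    )
    df.to_csv(path, index=False)


def build_matrix(
    triples: list[RelationTriple], catalog: RelationCatalog | None = None
) -> InteractionMatrix:
    """Aggregate relation triples into an :class:`InteractionMatrix`.

    Directional triples add their article count to ``counts[agent,
    theme]`` only; non-directional relations (per the catalog) add to both
    orientations.  All canonical relations for an ordered pair collapse
    into the same cell — the matrix is gene × gene, and the catalog's only
    role here is deciding directionality.
    """
    if not triples:
        raise ValueError("cannot build a matrix from an empty triple list")
    catalog = catalog or default_catalog()

    universe = sorted({t.agent for t in triples} | {t.theme for t in triples})
    index = GeneIndex(universe)
    rows: list[int] = []
    cols: list[int] = []
    data: list[int] = []
    for t in triples:
        i, j = index.row(t.agent), index.col(t.theme)
        rows.append(i)
        cols.append(j)
        data.append(t.article_count)
        if not catalog.is_directional(t.relation) and i != j:
            rows.append(j)
            cols.append(i)
            data.append(t.article_count)
    n = len(index)
    counts = sp.coo_matrix((data, (rows, cols)), shape=(n, n), dtype=np.int64)
    return InteractionMatrix(counts.tocsr(), index)
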