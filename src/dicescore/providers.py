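"""Pluggable retrieval providers for semi-automated informatic evidence.

Candidate literature/database support can be gathered by querying PubMed,
KEGG, GEO, GO or similar interfaces with a fixed query template (e.g.
``"{factor} and {phenotype}"``), so that searches stay consistent across
factors.  A hit only ever *proposes* an unreviewed evidence item — it never
awards points by itself: a human must review the hit and flip ``reviewed``
before the item scores under the default rubric.

Only the provider interface and an offline, table-backed fixture provider are
implemented here; live network clients (e.g. NCBI E-utilities) can be added as
adapters satisfying :class:`Provider`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Protocol

from dicescore.evidence_model import (
    Category,
    EvidenceItem,
    Factor,
    InformaticSubtype,
    Phenotype,
)

__all__ = [
    "Database",
    "EvidenceQuery",
    "QueryResult",
    "Provider",
    "FixtureProvider",
    "render_query",
    "search",
    "propose_items",
]


class Database(str, Enum):
    pubmed = "pubmed"
    kegg = "kegg"
    geo = "geo"
    go = "go"
    other = "other"


@dataclass(frozen=True)
class EvidenceQuery:
    factor_terms: tuple[str, ...]
    phenotype_terms: tuple[str, ...]
    database: Database
    raw_query: str


@dataclass(frozen=True)
class QueryResult:
    query: EvidenceQuery
    hit_count: int
    record_ids: tuple[str, ...] = ()
    retrieved_at: str = "fixture"
    in_fixture: bool = True

    def __post_init__(self) -> None:
        if self.hit_count < 0:
            raise ValueError("hit_count must be non-negative")
        if len(self.record_ids) > self.hit_count:
            raise ValueError("record_ids cannot exceed hit_count")


def render_query(
    factor: Factor,
    phenotype: Phenotype,
    database: Database,
    template: str = "{factor} and {phenotype}",
) -> EvidenceQuery:
    """Render a deterministic query from a fixed template.

    The first alias, when present, stands in for the factor name (searches
    usually use the spelled-out name, e.g. "tyrosine aminotransferase" for
    TAT).  The same inputs always render the identical raw query, which keeps
    searches comparable across factors.
    """
    if "{factor}" not in template or "{phenotype}" not in template:
        raise ValueError(
            "template must contain both {factor} and {phenotype} placeholders"
        )
    factor_terms = tuple(t for t in (factor.name, *factor.aliases) if t)
    phenotype_terms = (phenotype.name,) if phenotype.name else ()
    if not factor_terms:
        raise ValueError("factor must provide at least one search term")
    if not phenotype_terms:
        raise ValueError("phenotype must provide at least one search term")
    factor_term = factor.aliases[0] if factor.aliases else factor.name
    raw = template.format(factor=factor_term, phenotype=phenotype.name)
    return EvidenceQuery(
        factor_terms=factor_terms,
        phenotype_terms=phenotype_terms,
        database=database,
        raw_query=raw,
    )


class Provider(Protocol):
    """Interface a retrieval backend must satisfy."""

    database: Database

    def run(self, query: EvidenceQuery) -> QueryResult: ...


@dataclass
class FixtureProvider:
    """Offline provider answering from a raw_query -> record-ids table.

    The table format is two tab-separated columns: the raw query string and a
    comma-separated list of record ids (empty for zero hits).  Queries absent
    from the table return zero hits flagged ``in_fixture=False``.
    """

    database: Database = Database.pubmed
    table: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path: str | Path, database: Database = Database.pubmed):
        table: dict[str, tuple[str, ...]] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            raw_query, _, ids = line.partition("\t")
            record_ids = tuple(i.strip() for i in ids.split(",") if i.strip())
            table[raw_query] = record_ids
        return cls(database=database, table=table)

    def run(self, query: EvidenceQuery) -> QueryResult:
        if query.raw_query in self.table:
            ids = self.table[query.raw_query]
            return QueryResult(
                query=query, hit_count=len(ids), record_ids=ids, in_fixture=True
            )
        return QueryResult(query=query, hit_count=0, in_fixture=False)


def search(providers: dict[Database, Provider], query: EvidenceQuery) -> QueryResult:
    """Dispatch a query to the provider registered for its database."""
    provider = providers.get(query.database)
    if provider is None:
        raise KeyError(f"no provider registered for database {query.database.value!r}")
    return provider.run(query)


def propose_items(result: QueryResult) -> list[EvidenceItem]:
    """Turn a non-empty query result into one machine-proposed evidence item.

    The item is informatic/literature with ``reviewed=False``, so it cannot
    change a score until a human confirms it.  Zero hits propose nothing.
    """
    if result.hit_count < 1:
        return []
    q = result.query
    source = q.raw_query
    if result.record_ids:
        source += " [" + ", ".join(result.record_ids) + "]"
    item = EvidenceItem(
        item_id=f"proposed-{q.database.value}-{q.raw_query}",
        category=Category.informatic,
        subtype=InformaticSubtype.literature.value,
        result_key=f"{q.database.value}:{q.raw_query}",
        source=source,
        reviewed=False,
    )
    return [item]
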