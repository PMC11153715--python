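"""GO enrichment statistics, dictionary annotation, entity clouds, expansion.

Enrichment uses the one-sided (enrichment) Fisher exact test, i.e. the
hypergeometric tail P(X >= k), with Benjamini–Hochberg control over the
tested terms.  Entity annotation is a deterministic dictionary matcher:
leftmost-longest non-overlapping matches on token boundaries,
case-insensitive for terms of four or more characters and case-sensitive
for shorter symbols.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ENTITY_TYPES = frozenset(
    {"gene", "protein", "disease", "chemical", "phenotype", "anatomy", "food", "species"}
)

TABLE_SOURCES = ("ncbi", "uniprot", "stringdb", "go")


@dataclass
class AnnotationSet:
    """Gene→GO-term annotations over a background universe of genes."""

    gene_to_terms: dict[str, set[str]]
    background: set[str]
    term_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not set(self.gene_to_terms) <= self.background:
            raise ValueError("annotated genes must be a subset of the background")

    @property
    def term_to_genes(self) -> dict[str, set[str]]:
        inv: dict[str, set[str]] = {}
        for gene, terms in self.gene_to_terms.items():
            for term in terms:
                inv.setdefault(term, set()).add(gene)
        return inv

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        term_names: str | Path | None = None,
        background: Iterable[str] | None = None,
    ) -> "AnnotationSet":
        """Load gene<TAB>term rows (GAF-like, no header)."""
        df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"], dtype=str)
        g2t: dict[str, set[str]] = {}
        for row in df.itertuples(index=False):
            g2t.setdefault(row.gene, set()).add(row.term)
        names = {}
        if term_names is not None:
            ndf = pd.read_csv(
                term_names, sep="\t", header=None, names=["term", "name"], dtype=str
            )
            names = dict(zip(ndf.term, ndf.name))
        bg = set(background) if background is not None else set(g2t)
        return cls(gene_to_terms=g2t, background=bg, term_names=names)


@dataclass
class EnrichmentRow:
    term_id: str
    term_name: str
    k: int  # query genes annotated to the term
    n: int  # effective query size
    K: int  # background genes annotated to the term
    N: int  # background size
    p: float
    q: float
    significant: bool


@dataclass(frozen=True)
class EntityMention:
    """A dictionary hit with 0-based half-open character offsets."""

    start: int
    end: int
    surface: str
    entity_type: str
    concept_id: str


@dataclass
class Dictionary:
    """Term→concept lookup for :func:`annotate_text`.

    Entries are ``(term, concept_id, entity_type)``.  Loaded from a
    three-column TSV without header.
    """

    entries: list[tuple[str, str, str]]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Dictionary":
        df = pd.read_csv(
            path, sep="\t", header=None, names=["term", "id", "type"], dtype=str
        )
        return cls(entries=[(r.term, r.id, r.type) for r in df.itertuples(index=False)])


@dataclass
class EnrichmentTable:
    """Per-gene description texts and source URLs, one row per gene."""

    rows: dict[str, dict[str, str]]  # gene → {source: text, source_url: url}

    def texts(self, genes: Iterable[str] | None = None) -> list[str]:
        keys = sorted(self.rows) if genes is None else sorted(
            g for g in genes if g in self.rows
        )
        out = []
        for gene in keys:
            row = self.rows[gene]
            out.append(" ".join(row.get(src, "") for src in TABLE_SOURCES).strip())
        return out

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EnrichmentTable":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if "gene" not in df.columns:
            raise ValueError(f"enrichment table {path}: missing column 'gene'")
        rows = {}
        for rec in df.to_dict("records"):
            gene = rec.pop("gene")
            rows[gene] = rec
        return cls(rows=rows)

    def to_tsv(self, path: str | Path) -> None:
        cols = ["gene"]
        for src in TABLE_SOURCES:
            cols += [src, f"{src}_url"]
        records = []
        for gene in sorted(self.rows):
            rec = {"gene": gene}
            for col in cols[1:]:
                rec[col] = self.rows[gene].get(col, "")
            records.append(rec)
        pd.DataFrame(records, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Statistics


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up q-values, returned in input order.

    q_(i) = min_{j >= i} (m * p_(j) / j), capped at 1.
    """
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {p!r}")
    m = len(p_values)
    if m == 0:
        return []
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, m * p_values[i] / rank)
        q[i] = running_min
    return q


def go_enrichment(
    query: Iterable[str], ann: AnnotationSet, alpha: float = 0.05
) -> list[EnrichmentRow]:
    """Fisher exact GO enrichment of a gene set against the background.

    Genes outside the background are dropped with a warning.  Only terms
    overlapping the query (k >= 1) are tested; BH adjustment runs over the
    tested terms.  Rows are sorted by (q, p, term_id).
    """
    query_set = set(query)
    outside = query_set - ann.background
    if outside:
        logger.warning(
            "go_enrichment: %d query genes outside background dropped: %s",
            len(outside),
            ", ".join(sorted(outside)[:5]),
        )
    effective = query_set & ann.background
    if not effective:
        logger.warning("go_enrichment: empty effective query")
        return []

    N = len(ann.background)
    n = len(effective)
    term_to_genes = ann.term_to_genes

    tested: list[tuple[str, int, int]] = []
    for term, genes in term_to_genes.items():
        k = len(genes & effective)
        if k >= 1:
            tested.append((term, k, len(genes)))

    # one-sided enrichment p = P(X >= k) for X ~ Hypergeom(N, K, n)
    p_values = [float(stats.hypergeom.sf(k - 1, N, K, n)) for _, k, K in tested]
    q_values = bh_adjust(p_values)

    rows = [
        EnrichmentRow(
            term_id=term,
            term_name=ann.term_names.get(term, ""),
            k=k,
            n=n,
            K=K,
            N=N,
            p=p,
            q=q,
            significant=q < alpha,
        )
        for (term, k, K), p, q in zip(tested, p_values, q_values)
    ]
    rows.sort(key=lambda r: (r.q, r.p, r.term_id))
    return rows


def enrichment_to_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    cols = ["term_id", "term_name", "k", "n", "K", "N", "p", "q", "significant"]
    return pd.DataFrame(
        [[getattr(r, c) for c in cols] for r in rows], columns=cols
    )


# ---------------------------------------------------------------------------
# Dictionary annotation


def _is_word_char(c: str) -> bool:
    return c.isalnum()


def _token_starts_ends(text: str) -> tuple[set[int], set[int]]:
    starts, ends = set(), set()
    for i, c in enumerate(text):
        if _is_word_char(c) and (i == 0 or not _is_word_char(text[i - 1])):
            starts.add(i)
        if _is_word_char(c) and (i == len(text) - 1 or not _is_word_char(text[i + 1])):
            ends.add(i + 1)
    return starts, ends


def annotate_text(
    text: str, dictionaries: Dictionary | Sequence[Dictionary]
) -> list[EntityMention]:
    """Leftmost-longest non-overlapping dictionary matches on token boundaries."""
    if isinstance(dictionaries, Dictionary):
        dictionaries = [dictionaries]
    if not text:
        return []

    # index entries by match key; short symbols stay case-sensitive
    ci_entries: dict[str, tuple[str, str]] = {}
    cs_entries: dict[str, tuple[str, str]] = {}
    max_len = 0
    for d in dictionaries:
        for term, concept_id, entity_type in d.entries:
            if not term:
                continue
            max_len = max(max_len, len(term))
            if len(term) >= 4:
                ci_entries.setdefault(term.lower(), (concept_id, entity_type))
            else:
                cs_entries.setdefault(term, (concept_id, entity_type))

    starts, ends = _token_starts_ends(text)
    lower = text.lower()
    mentions: list[EntityMention] = []
    pos = 0
    while pos < len(text):
        if pos not in starts:
            pos += 1
            continue
        best: EntityMention | None = None
        limit = min(len(text), pos + max_len)
        for end in range(limit, pos, -1):
            if end not in ends:
                continue
            surface = text[pos:end]
            hit = None
            if len(surface) >= 4:
                hit = ci_entries.get(lower[pos:end])
            if hit is None:
                hit = cs_entries.get(surface)
            if hit is not None:
                best = EntityMention(
                    start=pos,
                    end=end,
                    surface=surface,
                    entity_type=hit[1],
                    concept_id=hit[0],
                )
                break  # longest match wins
        if best is not None:
            mentions.append(best)
            pos = best.end
        else:
            pos += 1
    return mentions


def entity_cloud(
    texts: Sequence[str] | EnrichmentTable,
    dictionaries: Dictionary | Sequence[Dictionary],
    entity_type: str | None = None,
) -> dict[str, int]:
    """Aggregate mention counts per concept, in descending count order."""
    if isinstance(texts, EnrichmentTable):
        texts = texts.texts()
    counts: Counter[str] = Counter()
    for text in texts:
        for mention in annotate_text(text, dictionaries):
            if entity_type is None or mention.entity_type == entity_type:
                counts[mention.concept_id] += 1
    return dict(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    )


def semantic_expand(
    seed_genes: Iterable[str],
    table: EnrichmentTable,
    dictionaries: Dictionary | Sequence[Dictionary],
    iterations: int = 1,
) -> set[str]:
    """Iteratively grow a gene set via gene mentions in its table texts.

    Each iteration annotates the description texts of the current genes and
    unions any gene-type concepts found; the set is monotone non-decreasing
    and reaches a fixed point once no new genes appear.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    genes = set(seed_genes)
    for _ in range(iterations):
        found: set[str] = set()
        for text in table.texts(genes):
            for mention in annotate_text(text, dictionaries):
                if mention.entity_type == "gene":
                    found.add(mention.concept_id)
        new = genes | found
        if new == genes:
            break
        genes = new
    return genes
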