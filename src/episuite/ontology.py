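"""Gene Ontology enrichment and redundancy pruning.

Enrichment of a query gene set against a universe is scored per term
with the upper-tail hypergeometric test after propagating gene
annotations to all ancestor terms (the true-path rule).  Because parent
and child terms annotated to nearly the same query genes clutter result
lists, an iterative pruning step discards any enriched term whose
enriched direct child covers most of the same query genes, keeping the
more specific term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .methstore import adjust_pvalues_bh

ONTOLOGIES = ("BP", "MF", "CC")


class GoDag:
    """A directed acyclic graph of GO terms (child -> is_a parents)."""

    def __init__(
        self,
        terms: Mapping[str, tuple[str, str]],  # id -> (name, ontology)
        edges: Mapping[str, Sequence[str]],  # child -> parents
    ):
        self.terms = dict(terms)
        self.parents: dict[str, tuple[str, ...]] = {
            t: tuple(edges.get(t, ())) for t in self.terms
        }
        for child, parents in self.parents.items():
            for p in parents:
                if p not in self.terms:
                    raise ValueError(f"edge {child}->{p}: parent not a known term")
                if self.terms[p][1] != self.terms[child][1]:
                    raise ValueError(f"edge {child}->{p} crosses ontologies")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(t: str, stack: list[str]) -> None:
            state[t] = 1
            for p in self.parents[t]:
                if state.get(p) == 1:
                    raise ValueError(f"cycle through {p} in GO DAG: {stack + [t, p]}")
                if state.get(p, 0) == 0:
                    visit(p, stack + [t])
            state[t] = 2

        for t in self.terms:
            if state.get(t, 0) == 0:
                visit(t, [])

    def ancestors(self, term: str) -> set[str]:
        """All (transitive) ancestors, excluding the term itself."""
        out: set[str] = set()
        frontier = list(self.parents[term])
        while frontier:
            p = frontier.pop()
            if p not in out:
                out.add(p)
                frontier.extend(self.parents[p])
        return out

    @classmethod
    def from_tsv(cls, path: str) -> "GoDag":
        """Read a DAG from a TSV of (child_id, parent_id, ontology) rows.

        A parent_id of "." or empty declares a root term with no parent.
        A fourth column, when present, names the child term.
        """
        terms: dict[str, tuple[str, str]] = {}
        edges: dict[str, list[str]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                child, parent, onto = f[0], f[1], f[2]
                name = f[3] if len(f) > 3 else child
                terms.setdefault(child, (name, onto))
                if parent not in (".", ""):
                    terms.setdefault(parent, (parent, onto))
                    edges.setdefault(child, []).append(parent)
        return cls(terms, edges)


def read_gene2term(path: str) -> dict[str, set[str]]:
    """TSV of (gene_id, term_id) rows -> gene -> direct term set."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gene, term = line.split("\t")[:2]
            out.setdefault(gene, set()).add(term)
    return out


@dataclass
class EnrichedTerm:
    term: str
    name: str
    ontology: str
    k: int  # query genes annotated (after propagation)
    K: int  # universe genes annotated
    n: int  # query size
    N: int  # universe size
    pvalue: float
    qvalue: float
    genes: frozenset


def propagate_annotations(
    gene2term: Mapping[str, set[str]], dag: GoDag
) -> dict[str, set[str]]:
    """Extend each gene's term set with all ancestors (true-path rule)."""
    out: dict[str, set[str]] = {}
    for gene, terms in gene2term.items():
        full = set()
        for t in terms:
            if t not in dag.terms:
                raise ValueError(f"term {t!r} absent from DAG")
            full.add(t)
            full |= dag.ancestors(t)
        out[gene] = full
    return out


def go_enrichment(
    query: Sequence[str],
    universe: Sequence[str],
    dag: GoDag,
    gene2term: Mapping[str, set[str]],
    ontology: Optional[str] = None,
) -> list[EnrichedTerm]:
    """Hypergeometric GO enrichment of a query set within a universe.

    For each term with at least one annotated universe gene, the p-value
    is P(X >= k) for X ~ Hypergeom(N, K, n); q-values are BH-corrected
    across the tested terms and results are sorted by p-value.
    """
    query_set = set(query)
    universe_set = set(universe)
    offenders = sorted(query_set - universe_set)
    if offenders:
        raise ValueError(f"query genes missing from universe: {offenders}")
    full = propagate_annotations(
        {g: t for g, t in gene2term.items() if g in universe_set}, dag
    )
    term_universe: dict[str, set[str]] = {}
    for gene, terms in full.items():
        for t in terms:
            term_universe.setdefault(t, set()).add(gene)
    N, n = len(universe_set), len(query_set)
    rows: list[EnrichedTerm] = []
    for t, members in sorted(term_universe.items()):
        if ontology is not None and dag.terms[t][1] != ontology:
            continue
        K = len(members)
        hit = members & query_set
        k = len(hit)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(EnrichedTerm(
            term=t, name=dag.terms[t][0], ontology=dag.terms[t][1],
            k=k, K=K, n=n, N=N, pvalue=p, qvalue=np.nan, genes=frozenset(hit),
        ))
    if rows:
        qvals = adjust_pvalues_bh([r.pvalue for r in rows])
        for r, q in zip(rows, qvals):
            r.qvalue = float(q)
    rows.sort(key=lambda r: (r.pvalue, r.term))
    return rows


def simplify_go_terms(
    enriched: Sequence[EnrichedTerm],
    dag: GoDag,
    overlap_threshold: float = 0.75,
    denominator: str = "child",
) -> list[EnrichedTerm]:
    """Drop enriched parents made redundant by an enriched child.

    Iterated to a fixed point: whenever a direct parent of an enriched
    term is itself enriched and the parent/child query-gene overlap
    exceeds ``overlap_threshold`` of the child's genes (``denominator``
    may instead name "parent" or "union"), the parent is discarded in
    favour of the more specific child.  The result does not depend on
    input order; children are never removed.
    """
    if denominator not in ("child", "parent", "union"):
        raise ValueError(f"unknown denominator {denominator!r}")
    for r in enriched:
        if r.term not in dag.terms:
            raise ValueError(f"term {r.term!r} absent from DAG")
    alive: dict[str, EnrichedTerm] = {r.term: r for r in enriched}
    changed = True
    while changed:
        changed = False
        # collect drops against the current state so order cannot matter
        to_drop: set[str] = set()
        for term, child in sorted(alive.items()):
            for parent in dag.parents[term]:
                if parent not in alive:
                    continue
                inter = len(child.genes & alive[parent].genes)
                denom = {
                    "child": len(child.genes),
                    "parent": len(alive[parent].genes),
                    "union": len(child.genes | alive[parent].genes),
                }[denominator]
                if denom and inter / denom > overlap_threshold:
                    to_drop.add(parent)
        if to_drop:
            for t in to_drop:
                del alive[t]
            changed = True
    return [r for r in enriched if r.term in alive]


def enrichment_to_tsv(rows: Sequence[EnrichedTerm], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("term\tname\tontology\tk\tK\tn\tN\tpvalue\tqvalue\tgenes\n")
        for r in rows:
            fh.write(
                f"{r.term}\t{r.name}\t{r.ontology}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
                f"{r.pvalue:.6e}\t{r.qvalue:.6e}\t{','.join(sorted(r.genes))}\n"
            )
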