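"""GO over-representation analysis with GO-slim summarisation.

The test is the classic (unconditional) hypergeometric upper tail: for a
term annotated to K of N universe genes and k of n study genes,

    p = sum_{i >= k} C(K, i) C(N-K, n-i) / C(N, n)

computed on the annotation *closure* — every gene counts toward all
is_a ancestors of its direct terms (the true-path rule).  Raw p-values
are reported (no multiple-testing correction by default; an FDR column
can be added by the caller).  The universe defaults to all genes with at
least one annotation.

GO-slim summarisation maps each enriched term to its minimal slim
ancestors: the slim terms on its is_a paths that have no other slim hit
below them.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet
import pandas as pd
from scipy import stats

__all__ = ["Ontology", "EnrichmentResult", "parse_obo",
           "propagate_annotations", "hypergeom_enrich", "goslim_summarize",
           "read_gene2go_tsv"]


@dataclass
class Ontology:
    """A DAG of GO terms connected by is_a edges.

    ``parents`` maps each term to its direct is_a parents; ``slim`` flags
    the summary subset.  Roots are the terms with no parents.
    """

    terms: dict              # id -> {"name": str, "namespace": str}
    parents: dict            # id -> tuple of parent ids
    slim: frozenset = frozenset()

    def __post_init__(self):
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, ps in self.parents.items():
            for p in ps:
                g.add_edge(child, p)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"is_a cycle detected: {cycle}")
        bad_slim = set(self.slim) - set(self.terms)
        if bad_slim:
            raise ValueError(f"slim terms not in ontology: {sorted(bad_slim)}")
        self._graph = g

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def ancestors(self, term: str) -> frozenset:
        """All strict is_a ancestors of a term."""
        return frozenset(nx.descendants(self._graph, term))

    def namespace_root(self, term: str) -> str:
        """The root term reachable from ``term`` (its namespace bucket)."""
        anc = [t for t in self.ancestors(term) | {term}
               if not self.parents.get(t)]
        return sorted(anc)[0]


def parse_obo(source) -> Ontology:
    """Parse a (minimal) OBO file or stream into an :class:`Ontology`.

    Only id/name/namespace/is_a/subset stanzas are used; obsolete terms
    are dropped.  Terms tagged with any ``subset`` are flagged as slim.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    graph = obonet.read_obo(source, ignore_obsolete=True)
    terms, parents, slim = {}, {}, set()
    for node, data in graph.nodes(data=True):
        terms[node] = {"name": data.get("name", node),
                       "namespace": data.get("namespace", "")}
        if data.get("subset"):
            slim.add(node)
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            parents.setdefault(child, []).append(parent)
    parents = {c: tuple(sorted(ps)) for c, ps in parents.items()}
    return Ontology(terms=terms, parents=parents, slim=frozenset(slim))


def propagate_annotations(
    gene2terms: Mapping[str, Iterable[str]], ontology: Ontology
) -> dict:
    """Close each gene's annotation set over is_a ancestors (idempotent)."""
    closure = {}
    anc_cache: dict = {}
    for gene, terms in gene2terms.items():
        out: set = set()
        for t in terms:
            if t not in ontology:
                warnings.warn(f"unknown term {t} on gene {gene}; skipped",
                              stacklevel=2)
                continue
            if t not in anc_cache:
                anc_cache[t] = ontology.ancestors(t) | {t}
            out |= anc_cache[t]
        closure[gene] = frozenset(out)
    return closure


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    name: str
    k: int   # study genes with the term
    K: int   # universe genes with the term
    n: int   # study size
    N: int   # universe size
    p: float

    def __post_init__(self):
        if self.k > min(self.K, self.n):
            raise ValueError("k exceeds min(K, n)")
        if not (0 < self.p <= 1):
            raise ValueError("p outside (0, 1]")


def hypergeom_enrich(
    study: Iterable[str],
    universe: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
    ontology: Ontology,
    p_thresh: float = 0.01,
) -> list[EnrichmentResult]:
    """Terms over-represented in the study set versus the universe.

    ``annotations`` are direct gene->term assignments; counting happens on
    the propagated closure.  Results with p < ``p_thresh`` are returned
    sorted by ascending p then term id.
    """
    study = set(study)
    universe = set(universe)
    if not study or not universe:
        raise ValueError("study and universe must be non-empty")
    if not study <= universe:
        raise ValueError("study set is not contained in the universe")
    closure = propagate_annotations(
        {g: ts for g, ts in annotations.items() if g in universe}, ontology)
    term_universe: dict = {}
    term_study: dict = {}
    for gene, terms in closure.items():
        for t in terms:
            term_universe[t] = term_universe.get(t, 0) + 1
            if gene in study:
                term_study[t] = term_study.get(t, 0) + 1
    N, n = len(universe), len(study)
    results = []
    for term, K in term_universe.items():
        k = term_study.get(term, 0)
        if k == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p = min(max(p, 5e-324), 1.0)
        if p < p_thresh:
            results.append(EnrichmentResult(
                term=term, name=ontology.terms[term]["name"],
                k=k, K=K, n=n, N=N, p=p))
    results.sort(key=lambda r: (r.p, r.term))
    return results


def goslim_summarize(
    enriched_terms: Iterable[str],
    ontology: Ontology,
    slim: Iterable[str] | None = None,
) -> dict:
    """Map each term to its minimal slim ancestors.

    A slim term is minimal for a term t when it lies on an is_a path from
    t (or is t itself) and no other slim hit of t is below it.  Terms with
    no slim ancestor bucket under their namespace root.  Returns
    slim term -> sorted list of enriched terms.
    """
    slim_set = frozenset(slim) if slim is not None else ontology.slim
    if not slim_set:
        raise ValueError("slim subset is empty")
    out: dict = {}
    for term in enriched_terms:
        hits = (ontology.ancestors(term) | {term}) & slim_set
        minimal = {s for s in hits
                   if not any(s in ontology.ancestors(o) for o in hits - {s})}
        if not minimal:
            minimal = {ontology.namespace_root(term)}
        for s in sorted(minimal):
            out.setdefault(s, []).append(term)
    return {s: sorted(ts) for s, ts in sorted(out.items())}


def read_gene2go_tsv(path) -> dict:
    """2-column TSV (gene, GO id) -> gene -> set of terms."""
    out: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, term = line.split("\t")[:2]
            out.setdefault(gene, set()).add(term)
    return out


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    rows = [{"term": r.term, "name": r.name, "k": r.k, "K": r.K,
             "n": r.n, "N": r.N, "p": r.p} for r in results]
    return pd.DataFrame(rows, columns=["term", "name", "k", "K", "n", "N", "p"])
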