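"""Superpathway assembly and per-cell-line network rewiring.

A *superpathway* is the union of many curated pathway edge lists (plus
optional screen-derived novel interactions) on a common gene-symbol
namespace. Per cell line, the superpathway is restricted to the genes that
are measured in the knockdown screen and not lost to deleterious mutation,
homozygous deletion, or absent expression; the retained nodes carry a
normalized protein essentiality ``p`` in [0, 1] (1 = most lethal knockdown
in that cell line).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

Edge = tuple[str, str]


def _canon(a: str, b: str) -> Edge:
    """Canonical unordered edge representation (sorted pair)."""
    return (a, b) if a <= b else (b, a)


@dataclass
class Superpathway:
    """Undirected simple graph of proteins with per-edge provenance.

    ``edge_provenance`` maps each canonical edge to the set of source
    labels (pathway names or ``"novel-screen"``) that contributed it. An
    edge present in k pathways appears once with k provenance labels.
    """

    nodes: set[str] = field(default_factory=set)
    edges: set[Edge] = field(default_factory=set)
    edge_provenance: dict[Edge, set[str]] = field(default_factory=dict)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(*e, provenance=sorted(self.edge_provenance.get(e, set())))
        return g

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class GeneEssentialityProfile:
    """One cell line's gene essentialities.

    ``raw`` is on the screen scale (more negative = more lethal knockdown);
    ``normalized`` maps each gene in ``raw`` to p in [0, 1], higher = more
    essential.
    """

    cell_line: str
    raw: dict[str, float]
    normalized: dict[str, float]


@dataclass
class CellLineContext:
    """Genes lost (mutation / homozygous deletion / no expression) and genes
    with essentiality measurements, for one cell line."""

    cell_line: str
    lost_genes: set[str] = field(default_factory=set)
    measured_genes: set[str] = field(default_factory=set)


@dataclass
class ContextNetwork:
    """Superpathway restricted to one cell line, essentiality on each node."""

    cell_line: str
    graph: nx.Graph
    node_essentiality: dict[str, float]


class MalformedEdgeError(ValueError):
    pass


def merge_pathways(
    pathway_edge_lists: Sequence[tuple[str, Iterable[tuple[str, str]]]],
    novel_edges: Iterable[tuple[str, str]] | None = None,
    symbol_map: Mapping[str, str] | None = None,
) -> Superpathway:
    """Union a collection of pathway edge lists into one superpathway.

    Parameters
    ----------
    pathway_edge_lists
        ``(pathway_name, edges)`` pairs; each edge is a pair of non-empty
        symbols.
    novel_edges
        Additional screen-derived interactions, annotated with provenance
        label ``"novel-screen"``.
    symbol_map
        Optional input-symbol -> official-symbol table. Symbols absent from
        the table are unmappable: they and their incident edges are dropped.
        Without a table, symbols pass through verbatim.

    Self-loops (homodimer annotations) are dropped with a warning: the
    line-graph transform downstream is ill-defined for them.
    """
    if not pathway_edge_lists and not novel_edges:
        raise ValueError("no pathway edge lists provided")

    sp = Superpathway()
    sources: list[tuple[str, Iterable[tuple[str, str]]]] = list(pathway_edge_lists)
    if novel_edges is not None:
        sources.append(("novel-screen", novel_edges))

    n_self_loops = 0
    n_unmapped = 0
    for name, edges in sources:
        for record in edges:
            try:
                a, b = record
            except (TypeError, ValueError) as exc:
                raise MalformedEdgeError(
                    f"malformed edge record {record!r} in pathway {name!r}"
                ) from exc
            if not a or not b:
                raise MalformedEdgeError(
                    f"empty symbol in edge record {record!r} in pathway {name!r}"
                )
            if symbol_map is not None:
                if a not in symbol_map or b not in symbol_map:
                    # the mappable endpoint is still a valid network node
                    for s in (a, b):
                        if s in symbol_map:
                            sp.nodes.add(symbol_map[s])
                    n_unmapped += 1
                    continue
                a, b = symbol_map[a], symbol_map[b]
            if a == b:
                sp.nodes.add(a)
                n_self_loops += 1
                continue
            e = _canon(a, b)
            sp.nodes.update(e)
            sp.edges.add(e)
            sp.edge_provenance.setdefault(e, set()).add(name)

    if n_self_loops:
        logger.warning("dropped %d self-loop edge(s)", n_self_loops)
    if n_unmapped:
        logger.warning("excised %d edge(s) with unmappable symbols", n_unmapped)
    return sp


def collapse_shrna_to_gene(
    shrna_scores: Mapping[str, Sequence[float]],
) -> dict[str, float]:
    """Gene-level score = second most lethal (second smallest) hairpin score.

    Using the second order statistic suppresses single-hairpin off-target
    artifacts. Genes with fewer than two hairpins carry no multi-hairpin
    validation and are excluded.
    """
    out: dict[str, float] = {}
    excluded = []
    for gene, scores in shrna_scores.items():
        scores = list(scores)
        if len(scores) < 2:
            excluded.append(gene)
            continue
        out[gene] = sorted(scores)[1]
    if excluded:
        logger.warning(
            "excluded %d gene(s) with fewer than 2 shRNAs", len(excluded)
        )
    return out


def normalize_protein_essentiality(raw: Mapping[str, float]) -> dict[str, float]:
    """Map screen-scale scores to p in [0, 1] per cell line.

    p = (max_raw - x) / (max_raw - min_raw): negation plus min-max, so the
    most lethal gene in the cell line gets p = 1 and the least lethal p = 0.
    A degenerate all-equal profile maps every gene to the midpoint 0.5 so
    the exponential edge kernel stays defined.
    """
    if not raw:
        raise ValueError("empty essentiality profile")
    values = list(raw.values())
    lo, hi = min(values), max(values)
    if hi == lo:
        logger.warning("all raw essentialities identical; assigning p = 0.5")
        return {g: 0.5 for g in raw}
    span = hi - lo
    return {g: (hi - x) / span for g, x in raw.items()}


class EmptyContextError(ValueError):
    pass


def apply_context(
    sp: Superpathway,
    ctx: CellLineContext,
    profile: GeneEssentialityProfile,
) -> ContextNetwork:
    """Restrict the superpathway to one cell line's retained genes.

    Nodes are removed (with all incident edges) if they are in the
    context's lost set or lack an essentiality measurement; the remaining
    nodes carry normalized essentiality from ``profile``.
    """
    if profile.cell_line != ctx.cell_line:
        raise ValueError(
            f"profile cell line {profile.cell_line!r} != context {ctx.cell_line!r}"
        )
    measured = set(profile.normalized) & ctx.measured_genes if ctx.measured_genes else set(profile.normalized)
    retained = {
        n for n in sp.nodes if n not in ctx.lost_genes and n in measured
    }
    if not retained:
        n_lost = len(sp.nodes & ctx.lost_genes)
        n_unmeasured = len(sp.nodes - measured)
        raise EmptyContextError(
            f"context network for {ctx.cell_line!r} is empty "
            f"({n_lost} node(s) lost, {n_unmeasured} unmeasured)"
        )
    g = nx.Graph()
    g.add_nodes_from(retained)
    g.add_edges_from(e for e in sp.edges if e[0] in retained and e[1] in retained)
    ess = {n: profile.normalized[n] for n in retained}
    nx.set_node_attributes(g, ess, "essentiality")
    return ContextNetwork(cell_line=ctx.cell_line, graph=g, node_essentiality=ess)


def make_profile(cell_line: str, raw: Mapping[str, float]) -> GeneEssentialityProfile:
    """Convenience: build a profile with its normalized scores attached."""
    return GeneEssentialityProfile(
        cell_line=cell_line,
        raw=dict(raw),
        normalized=normalize_protein_essentiality(raw),
    )


def expression_lost_genes(
    expression: Mapping[str, float], threshold: float = 0.0
) -> set[str]:
    """Genes considered unexpressed: value <= threshold (log-scale default 0).

    The cutoff is user-set; pass the threshold appropriate to the matrix's
    scale.
    """
    return {g for g, v in expression.items() if v <= threshold}
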