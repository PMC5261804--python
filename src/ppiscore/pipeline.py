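"""End-to-end workflow: screen file + superpathway + contexts -> matrix.

Per cell line: collapse hairpins to gene scores (second most lethal),
normalize to p in [0, 1], restrict the superpathway to the retained genes,
build the line graph, propagate, and stack the converged scores into the
PPIs x cell lines essentiality matrix (NaN where a PPI left the context).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import io as pio
from .engine import PropagationConfig, ScoreVector, score_context_network
from .metrics import assemble_matrix
from .pathway_network import (
    CellLineContext,
    EmptyContextError,
    Superpathway,
    apply_context,
    collapse_shrna_to_gene,
    make_profile,
)

logger = logging.getLogger(__name__)


def score_cell_line(
    sp: Superpathway,
    gct: pd.DataFrame,
    cell_line: str,
    ctx: CellLineContext | None = None,
    cfg: PropagationConfig | None = None,
) -> ScoreVector:
    """PPI essentiality scores for one cell line of a hairpin-level screen."""
    cfg = cfg or PropagationConfig()
    shrna = pio.gct_to_shrna_scores(gct, cell_line)
    gene_scores = collapse_shrna_to_gene(shrna)
    profile = make_profile(cell_line, gene_scores)
    if ctx is None:
        ctx = CellLineContext(cell_line=cell_line, lost_genes=set(), measured_genes=set(gene_scores))
    elif not ctx.measured_genes:
        ctx = CellLineContext(
            cell_line=cell_line, lost_genes=ctx.lost_genes, measured_genes=set(gene_scores)
        )
    net = apply_context(sp, ctx, profile)
    return score_context_network(net, cfg)


def build_matrix(
    sp: Superpathway,
    gct: pd.DataFrame,
    contexts: Mapping[str, CellLineContext] | None = None,
    cell_lines: Sequence[str] | None = None,
    cfg: PropagationConfig | None = None,
) -> pd.DataFrame:
    """Essentiality matrix over many cell lines.

    Cell lines whose context network comes out empty are skipped with a
    warning rather than failing the whole run.
    """
    cfg = cfg or PropagationConfig()
    if cell_lines is None:
        cell_lines = [c for c in gct.columns if c != "gene"]
    vectors = []
    for cl in cell_lines:
        ctx = (contexts or {}).get(cl)
        try:
            vectors.append(score_cell_line(sp, gct, cl, ctx=ctx, cfg=cfg))
        except EmptyContextError as exc:
            logger.warning("skipping %s: %s", cl, exc)
    if not vectors:
        raise EmptyContextError("every cell line produced an empty context network")
    return assemble_matrix(vectors)


def normalized_profiles(
    gct: pd.DataFrame, cell_lines: Iterable[str] | None = None
) -> dict[str, dict[str, float]]:
    """Per-cell-line normalized gene essentialities (for MPER)."""
    if cell_lines is None:
        cell_lines = [c for c in gct.columns if c != "gene"]
    out = {}
    for cl in cell_lines:
        gene_scores = collapse_shrna_to_gene(pio.gct_to_shrna_scores(gct, cl))
        out[cl] = make_profile(cl, gene_scores).normalized
    return out
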