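"""Essentiality-matrix assembly, filtering, rankings, MPER and KS statistics.

The essentiality matrix is a pandas DataFrame with one row per PPI (index
``"SYMBOL1_SYMBOL2"``, partners sorted alphabetically), one column per cell
line, values in [0, 1] and NaN exactly where the PPI is absent from that
cell line's context network (a partner deleted, deleteriously mutated,
unexpressed, or unmeasured).

MPER (max-protein-essentiality ratio) compares a PPI's essentiality to the
stronger of its two partner proteins' knockdown essentialities. Both sides
are put on the rank-percentile scale first, to avoid consistent magnitude
biases between the two kinds of score; MPER > 1 flags interactions more
critical than either partner's knockdown alone suggests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .engine import ScoreVector

logger = logging.getLogger(__name__)


def ppi_key(a: str, b: str) -> str:
    """Canonical row key for a PPI: sorted symbols joined by '_'.

    Symbols containing '_' are rejected: the key could not be split back.
    """
    for s in (a, b):
        if "_" in s:
            raise ValueError(f"gene symbol {s!r} contains '_'; cannot form PPI key")
    return "_".join(sorted((a, b)))


def split_ppi_key(key: str) -> tuple[str, str]:
    a, _, b = key.partition("_")
    if not a or not b or "_" in b:
        raise ValueError(f"malformed PPI key {key!r}")
    return a, b


def assemble_matrix(score_vectors: Iterable[ScoreVector]) -> pd.DataFrame:
    """Stack per-cell-line score vectors into the PPIs x cell lines matrix.

    A PPI absent from a cell line's context network gets NaN in that column.
    """
    columns = {}
    for sv in score_vectors:
        if sv.cell_line is None:
            raise ValueError("score vector lacks a cell line label")
        columns[sv.cell_line] = {ppi_key(*p): v for p, v in sv.scores.items()}
    if not columns:
        raise ValueError("no score vectors supplied")
    mat = pd.DataFrame(columns).sort_index()
    return mat


def filter_cell_lines(matrix: pd.DataFrame, max_missing_fraction: float = 0.2) -> pd.DataFrame:
    """Drop cell lines (columns) with strictly more than the allowed missing fraction."""
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    frac = matrix.isna().mean(axis=0)
    keep = frac.index[frac <= max_missing_fraction]
    if len(keep) == 0:
        raise ValueError("all cell lines exceed the missing-fraction threshold")
    return matrix.loc[:, keep]


def filter_uniform_ppis(matrix: pd.DataFrame, epsilon: float = 1e-12) -> pd.DataFrame:
    """Drop PPIs (rows) with uniform essentiality across cell lines.

    Uniformity is SD <= epsilon over the non-missing entries; rows with a
    single present value have SD 0 and are dropped too.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    sd = matrix.std(axis=1, ddof=0, skipna=True).fillna(0.0)
    return matrix.loc[sd.values > epsilon]


def rank_percentiles(values: pd.Series | Mapping[str, float] | np.ndarray) -> pd.Series:
    """Percentile = rank / n over non-missing values, average ranks for ties.

    Missing entries stay missing; the maximum percentile is exactly 1.
    """
    s = pd.Series(values, dtype=float)
    n = s.notna().sum()
    if n == 0:
        raise ValueError("no non-missing values to rank")
    return s.rank(method="average", na_option="keep") / n


@dataclass
class MPERRecord:
    ppi: str
    cell_line: str
    ppi_percentile: float
    max_protein_percentile: float
    mper: float


def compute_mper(
    ppi_scores: pd.Series | Mapping[str, float],
    protein_essentiality: Mapping[str, float],
    cell_line: str = "",
) -> list[MPERRecord]:
    """MPER for every PPI of one cell line.

    ``ppi_scores``: PPI key -> essentiality (NaN/missing PPIs skipped).
    ``protein_essentiality``: gene -> normalized p for the same cell line.
    MPER = percentile of the PPI among all PPIs divided by the percentile of
    the more essential partner among all proteins.
    """
    s = pd.Series(ppi_scores, dtype=float).dropna()
    if s.empty:
        return []
    ppi_pct = rank_percentiles(s)
    prot_pct = rank_percentiles(pd.Series(dict(protein_essentiality), dtype=float))
    records: list[MPERRecord] = []
    for key, pct in ppi_pct.items():
        a, b = split_ppi_key(key)
        if a not in prot_pct.index or b not in prot_pct.index:
            logger.warning(
                "partner protein missing from profile for PPI %s in %s; skipped",
                key, cell_line,
            )
            continue
        mp = max(prot_pct[a], prot_pct[b])
        records.append(
            MPERRecord(
                ppi=key,
                cell_line=cell_line,
                ppi_percentile=float(pct),
                max_protein_percentile=float(mp),
                mper=float(pct / mp),
            )
        )
    return records


def mper_table(
    matrix: pd.DataFrame, profiles: Mapping[str, Mapping[str, float]]
) -> pd.DataFrame:
    """MPER records for every cell line of a matrix, as one long DataFrame.

    ``profiles`` maps cell line -> (gene -> normalized essentiality).
    """
    frames = []
    for cl in matrix.columns:
        recs = compute_mper(matrix[cl], profiles[cl], cell_line=cl)
        if recs:
            frames.append(pd.DataFrame([r.__dict__ for r in recs]))
    if not frames:
        return pd.DataFrame(
            columns=["ppi", "cell_line", "ppi_percentile", "max_protein_percentile", "mper"]
        )
    return pd.concat(frames, ignore_index=True)


def ks_rank_statistic(percentiles: Iterable[float]) -> float:
    """Signed sup-deviation of rank percentiles from the uniform distribution.

    For sorted percentiles u_(1) <= ... <= u_(n) against the uniform CDF:

        D_high = max_i ( u_(i) - (i - 1) / n )   (ECDF below the diagonal;
                                                  ranks concentrated high)
        D_low  = max_i ( i / n - u_(i) )         (ranks concentrated low)

    Returns +D_high when the sample sits above uniform (consistently
    top-ranked; values near +1), else -D_low. Both sups are taken over the
    ECDF jump points (right-limit convention at u = 1, so an all-ones
    sample returns exactly 1.0).
    """
    u = np.sort(np.asarray(list(percentiles), dtype=float))
    n = u.size
    if n == 0:
        raise ValueError("empty percentile list")
    i = np.arange(1, n + 1)
    d_high = np.max(u - (i - 1) / n)
    d_low = np.max(i / n - u)
    return float(d_high) if d_high >= d_low else -float(d_low)


def ks_by_group(matrix: pd.DataFrame, group_cell_lines: Iterable[str]) -> pd.Series:
    """Per-PPI KS rank statistic over a cell-line group (e.g. LUAD lines).

    Percentiles are computed within each cell line across PPIs, then the KS
    statistic of each PPI's percentile sample across the group's lines.
    """
    cols = [c for c in group_cell_lines if c in matrix.columns]
    if not cols:
        raise ValueError("no group cell lines present in matrix")
    pct = matrix[cols].apply(rank_percentiles, axis=0)
    out = {}
    for ppi, row in pct.iterrows():
        vals = row.dropna()
        out[ppi] = ks_rank_statistic(vals.values) if len(vals) else np.nan
    return pd.Series(out, name="ks")


def top_ppis(matrix: pd.DataFrame, min_mean: float = 0.5) -> pd.DataFrame:
    """PPIs with mean essentiality (over non-missing lines) above min_mean.

    Sorted descending by mean; ties broken lexicographically by PPI key.
    """
    if matrix.empty:
        raise ValueError("empty matrix")
    means = matrix.mean(axis=1, skipna=True)
    sel = means[means > min_mean]
    df = sel.rename("mean_essentiality").to_frame()
    df["_key"] = df.index
    df = df.sort_values(["mean_essentiality", "_key"], ascending=[False, True])
    return df.drop(columns="_key")


def median_center(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise median centering, the standard preprocessing before clustering."""
    return matrix.sub(matrix.median(axis=1, skipna=True), axis=0)
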