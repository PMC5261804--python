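"""Validation screens: drug-target enrichment, differential essentiality,
and PPI-presence survival analysis.

Three independent screens probe whether inferred PPI essentialities carry
biological signal:

* **Drug screen** — per compound, are the essentialities of PPIs touching a
  known target gene shifted above the non-target PPIs (one-sided rank-sum),
  and how often does a random target set of the same size do as well
  (permutation FDR)? Pearson correlation of a PPI's essentiality with
  compound sensitivity (AUC) across cell lines is available per pair.
* **Mutation screen** — mutant vs wild-type cell lines, per-PPI Welch t
  test with Benjamini-Hochberg adjustment.
* **Survival screen** — patients split by whether a PPI is intact (absent
  iff a partner gene carries a nonsense mutation, frameshift mutation, or
  homozygous deletion); two-group log-rank test per PPI, implemented from
  the risk-table definition; Benjamini-Yekutieli adjustment across PPIs
  (valid under arbitrary dependence between the overlapping PPI splits).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .metrics import split_ppi_key

logger = logging.getLogger(__name__)

DISRUPTING_VARIANTS = frozenset({"nonsense", "frameshift"})
KNOWN_VARIANTS = frozenset(
    {"nonsense", "frameshift", "missense", "silent", "splice_site", "inframe_indel"}
)
HOMOZYGOUS_DELETION = "homozygous_deletion"


@dataclass
class AssociationResult:
    """One screen result: a unit (PPI or compound), its statistic and p-values."""

    unit: str
    statistic: float
    p_value: float
    adjusted: float | None = None
    n: int = 0
    evaluable: bool = True
    note: str = ""


@dataclass
class DrugScreenInput:
    """Sensitivity AUCs (compounds x cell lines) plus compound -> target genes."""

    auc: pd.DataFrame
    targets: dict[str, set[str]] = field(default_factory=dict)


@dataclass
class PatientPPIStatus:
    patient: str
    ppi: str
    present: bool
    time: float
    event: bool


# --------------------------------------------------------------------------
# drug screen


def correlate_drug_sensitivity(
    ppi_scores: pd.Series, auc: pd.Series
) -> tuple[float, float, int]:
    """Pearson correlation of one PPI's essentiality with one compound's AUC.

    Cell lines where either value is missing (the PPI absent from that
    line's context network, or the compound unscreened) are excluded.
    Returns (r, two-sided p from the t transform with n-2 df, n).
    """
    df = pd.concat({"e": ppi_scores, "a": auc}, axis=1).dropna()
    n = len(df)
    if n < 3:
        raise ValueError(f"need >= 3 cell lines with both values, got {n}")
    if df["e"].nunique() == 1 or df["a"].nunique() == 1:
        raise ValueError("zero variance in essentiality or AUC vector")
    r, p = stats.pearsonr(df["e"], df["a"])
    return float(r), float(p), n


def rank_sum_test(
    a: np.ndarray, b: np.ndarray, alternative: str = "greater", method: str = "asymptotic"
) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney U of group a vs b).

    Returns (U statistic of group a, p-value); asymptotic p uses the normal
    approximation with tie correction, ``method="exact"`` enumerates (small
    samples without ties only).
    """
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def _ranksum_z(pooled_ranks: np.ndarray, mask_a: np.ndarray, tie_term: float) -> float:
    """Standardized one-sided rank-sum score for group A (higher = A larger).

    ``pooled_ranks`` are average ranks of the pooled sample; ``tie_term`` is
    sum(t^3 - t) over tie groups, precomputed since the pool is fixed.
    """
    n = pooled_ranks.size
    n_a = int(mask_a.sum())
    n_b = n - n_a
    r_a = pooled_ranks[mask_a].sum()
    u = r_a - n_a * (n_a + 1) / 2.0
    mean = n_a * n_b / 2.0
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 0.0
    return (u - mean) / np.sqrt(var)


def target_enrichment(
    matrix: pd.DataFrame,
    targets: set[str],
    n_perm: int = 1000,
    seed: int | None = None,
    compound: str = "",
) -> AssociationResult:
    """Are target-touching PPIs more essential than the rest?

    Group A pools all non-missing essentiality values of PPIs with at least
    one partner in ``targets``; group B the values of all other PPIs. The
    one-sided rank-sum (A > B) gives the nominal p (normal approximation);
    the permutation FDR redraws ``len(targets & universe)`` genes uniformly
    from the network's gene universe ``n_perm`` times and reports the
    fraction of redraws whose standardized statistic meets or exceeds the
    observed one, floored at 1 / n_perm.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if matrix.empty:
        raise ValueError("empty essentiality matrix")
    partners = [split_ppi_key(k) for k in matrix.index]
    universe = sorted({g for pair in partners for g in pair})
    hit_targets = set(targets) & set(universe)
    in_a = np.array([(a in targets) or (b in targets) for a, b in partners])
    if not in_a.any():
        return AssociationResult(
            unit=compound, statistic=np.nan, p_value=np.nan, adjusted=np.nan,
            n=0, evaluable=False, note="no target PPIs in network",
        )
    if in_a.all():
        raise ValueError("targets cover every PPI; non-target group is empty")

    values = matrix.to_numpy(dtype=float)
    present = ~np.isnan(values)
    flat = values[present]
    row_of = np.repeat(np.arange(values.shape[0]), values.shape[1]).reshape(values.shape)[present]
    ranks = stats.rankdata(flat)
    _, counts = np.unique(flat, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))

    mask_a = in_a[row_of]
    a_vals, b_vals = flat[mask_a], flat[~mask_a]
    u_stat, p = rank_sum_test(a_vals, b_vals, alternative="greater")
    z_obs = _ranksum_z(ranks, mask_a, tie_term)

    # permutation: redraw a target set of the same size from the gene universe
    rng = np.random.default_rng(seed)
    gene_arr = np.array(universe)
    pair_a = np.array([a for a, _ in partners])
    pair_b = np.array([b for _, b in partners])
    n_exceed = 0
    k = len(hit_targets)
    for _ in range(n_perm):
        perm_targets = set(rng.choice(gene_arr, size=k, replace=False))
        perm_in_a = np.isin(pair_a, list(perm_targets)) | np.isin(pair_b, list(perm_targets))
        perm_mask = perm_in_a[row_of]
        if not perm_mask.any() or perm_mask.all():
            continue
        if _ranksum_z(ranks, perm_mask, tie_term) >= z_obs:
            n_exceed += 1
    fdr = max(n_exceed / n_perm, 1.0 / n_perm)
    return AssociationResult(
        unit=compound, statistic=float(u_stat), p_value=p, adjusted=float(fdr),
        n=int(a_vals.size + b_vals.size),
        note="" if n_exceed else f"<{1.0 / n_perm:g}",
    )


def drug_screen(
    matrix: pd.DataFrame,
    screen: DrugScreenInput,
    n_perm: int = 1000,
    seed: int | None = None,
) -> list[AssociationResult]:
    """Target enrichment for every compound of a drug screen."""
    ss = np.random.SeedSequence(seed)
    results = []
    for compound, child in zip(sorted(screen.targets), ss.spawn(len(screen.targets))):
        results.append(
            target_enrichment(
                matrix, screen.targets[compound], n_perm=n_perm,
                seed=int(child.generate_state(1)[0] % (2**31)), compound=compound,
            )
        )
    return results


# --------------------------------------------------------------------------
# mutation screen


def differential_essentiality(
    matrix: pd.DataFrame, group_labels: Mapping[str, str]
) -> list[AssociationResult]:
    """Per-PPI mutant vs wild-type Welch t test with BH adjustment.

    ``group_labels`` maps cell line -> "mutant" | "wildtype". PPIs with
    fewer than 2 non-missing values in either group are skipped. Results
    are sorted by adjusted p; positive statistic = more essential in
    mutants.
    """
    mut_cols = [c for c in matrix.columns if group_labels.get(c) == "mutant"]
    wt_cols = [c for c in matrix.columns if group_labels.get(c) == "wildtype"]
    if not mut_cols or not wt_cols:
        raise ValueError("both mutant and wildtype groups must be non-empty")
    A = matrix[mut_cols].to_numpy(dtype=float)
    B = matrix[wt_cols].to_numpy(dtype=float)
    n_a = np.sum(~np.isnan(A), axis=1)
    n_b = np.sum(~np.isnan(B), axis=1)
    ok = (n_a >= 2) & (n_b >= 2)
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.warning("skipped %d PPI(s) with < 2 values in a group", n_skipped)
    if not ok.any():
        return []
    t, p = stats.ttest_ind(
        A[ok], B[ok], axis=1, equal_var=False, nan_policy="omit"
    )
    t, p = np.asarray(t, dtype=float), np.asarray(p, dtype=float)
    finite = np.isfinite(p)
    if not finite.all():
        # degenerate rows (e.g. zero variance in both groups) have no defined t
        logger.warning("skipped %d PPI(s) with undefined test statistic", int((~finite).sum()))
        idx = np.flatnonzero(ok)
        ok[idx[~finite]] = False
        t, p = t[finite], p[finite]
    if not ok.any():
        return []
    adj = multipletests(p, method="fdr_bh")[1]
    units = matrix.index[ok]
    results = [
        AssociationResult(
            unit=u, statistic=float(ti), p_value=float(pi), adjusted=float(ai),
            n=int(na + nb),
        )
        for u, ti, pi, ai, na, nb in zip(units, t, p, adj, n_a[ok], n_b[ok])
    ]
    results.sort(key=lambda r: (r.adjusted, r.p_value, r.unit))
    return results


# --------------------------------------------------------------------------
# survival screen


def ppi_presence_from_patient(
    mutations: Iterable[tuple[str, str, str]], ppi: tuple[str, str] | str
) -> bool:
    """Is a PPI intact in a patient, given that patient's alteration records?

    ``mutations`` holds (gene, variant_class, copy_state) records. The PPI
    is absent iff either partner carries a nonsense or frameshift mutation
    or a homozygous deletion; missense and other non-truncating classes do
    not remove it. Unknown variant classes are ignored with a warning.
    """
    if isinstance(ppi, str):
        partners = set(split_ppi_key(ppi))
    else:
        partners = set(ppi)
    for gene, variant_class, copy_state in mutations:
        if gene not in partners:
            continue
        if copy_state == HOMOZYGOUS_DELETION:
            return False
        if variant_class in DISRUPTING_VARIANTS:
            return False
        if variant_class and variant_class not in KNOWN_VARIANTS:
            logger.warning("unknown variant class %r ignored", variant_class)
    return True


def patient_status_records(
    mutations: pd.DataFrame,
    clinical: pd.DataFrame,
    ppis: Iterable[str],
) -> list[PatientPPIStatus]:
    """Cross patients with PPIs into presence/survival records.

    ``mutations`` has columns (patient, gene, variant_class, copy_state);
    ``clinical`` has (patient, time_days, event). Every patient in the
    clinical table contributes one record per PPI; patients with no
    alteration records retain every PPI.
    """
    muts_by_patient: dict[str, list[tuple[str, str, str]]] = {}
    for _, row in mutations.iterrows():
        muts_by_patient.setdefault(row["patient"], []).append(
            (row["gene"], row["variant_class"], row["copy_state"])
        )
    records = []
    for _, row in clinical.iterrows():
        pid = row["patient"]
        pmuts = muts_by_patient.get(pid, [])
        for ppi in ppis:
            records.append(
                PatientPPIStatus(
                    patient=pid,
                    ppi=ppi,
                    present=ppi_presence_from_patient(pmuts, ppi),
                    time=float(row["time_days"]),
                    event=bool(int(row["event"])),
                )
            )
    return records


def logrank_test(
    times: Sequence[float], events: Sequence[bool], groups: Sequence
) -> tuple[float, float]:
    """Two-group log-rank test from the risk-table definition.

    At each distinct event time t with d events among N at risk (d_1 of
    them in group 1, N_1 at risk in group 1), the group-1 expectation is
    d * N_1 / N and the hypergeometric variance
    d * (N_1/N) * (1 - N_1/N) * (N - d) / (N - 1). The statistic is
    (sum(O - E))^2 / sum(V), chi-square with 1 df. Ties are handled by
    simultaneous risk-set accounting at each distinct time.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(groups)
    if t.size != e.size or t.size != g.size:
        raise ValueError("times, events and groups must have equal length")
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    levels = np.unique(g)
    if levels.size != 2:
        raise ValueError(f"need exactly two groups, got {levels.size}")
    in1 = g == levels[0]
    o_minus_e = 0.0
    var = 0.0
    for tau in np.unique(t[e]):
        at_risk = t >= tau
        N = int(at_risk.sum())
        N1 = int((at_risk & in1).sum())
        d = int((e & (t == tau)).sum())
        d1 = int((e & (t == tau) & in1).sum())
        o_minus_e += d1 - d * N1 / N
        if N > 1:
            var += d * (N1 / N) * (1 - N1 / N) * (N - d) / (N - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def by_correction(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjustment, valid under any dependence.

    adjusted_(i) = min over j >= i of min(1, p_(j) * m * c(m) / j) with the
    harmonic factor c(m) = sum_{k=1..m} 1/k; monotone and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m * c_m / np.arange(1, m + 1)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


def qq_expected(p_values: Sequence[float]) -> pd.DataFrame:
    """Observed vs expected p-value quantiles for a QQ plot.

    Observed = sorted p ascending; expected_i = i / (m + 1). Columns with
    the -log10 transform are included for plotting.
    """
    p = np.sort(np.asarray(p_values, dtype=float))
    m = p.size
    if m == 0:
        raise ValueError("empty p-value list")
    expected = np.arange(1, m + 1) / (m + 1)
    with np.errstate(divide="ignore"):
        return pd.DataFrame(
            {
                "expected": expected,
                "observed": p,
                "neglog10_expected": -np.log10(expected),
                "neglog10_observed": -np.log10(p),
            }
        )


def survival_screen(
    status: Iterable[PatientPPIStatus],
    ks_stats: Mapping[str, float],
    ks_threshold: float = 0.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-PPI presence/absence log-rank screen, gated on rank enrichment.

    For each PPI, patients are split by ``present``; the two-group log-rank
    p is computed, BY-adjusted across all evaluable PPIs, and PPIs passing
    both gates (nominal p < alpha and KS rank statistic > ks_threshold in
    the tumor-matched cell lines) are returned sorted by nominal p. The
    full per-PPI table is in the result regardless of gating via the
    ``passes`` column.
    """
    by_ppi: dict[str, list[PatientPPIStatus]] = {}
    for rec in status:
        by_ppi.setdefault(rec.ppi, []).append(rec)
    rows = []
    for ppi in sorted(by_ppi):
        recs = by_ppi[ppi]
        groups = np.array([r.present for r in recs])
        if groups.all() or not groups.any():
            rows.append((ppi, np.nan, np.nan, len(recs), False))
            continue
        chi2, p = logrank_test(
            [r.time for r in recs], [r.event for r in recs], groups
        )
        rows.append((ppi, chi2, p, len(recs), True))
    df = pd.DataFrame(
        rows, columns=["ppi", "chi2", "p", "n", "evaluable"]
    ).set_index("ppi")
    df["p_by"] = np.nan
    ev = df["evaluable"]
    if ev.any():
        df.loc[ev, "p_by"] = by_correction(df.loc[ev, "p"].to_numpy())
    df["ks"] = pd.Series(ks_stats).reindex(df.index)
    df["passes"] = ev & (df["p"] < alpha) & (df["ks"] > ks_threshold)
    return df.sort_values(["p", "ppi"], na_position="last")
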