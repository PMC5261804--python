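"""Seed-reproducible synthetic inputs with the structure the method assumes.

The generator emulates the shape of the real inputs end to end: a
multi-pathway protein network with hub-heavy overlap (union of
preferential-attachment subnetworks sharing designated hub genes),
hairpin-level knockdown scores on the screen scale (more negative = more
lethal) with a few strongly essential hubs, per-cell-line loss contexts
(deleterious mutation / homozygous deletion / no expression), a drug
screen with one compound whose sensitivity AUC is planted to correlate
with its target gene's essentiality, and a patient cohort whose survival
hazard depends on whether one planted PPI is intact.

One master seed fans out to independent substreams (network, essentiality,
contexts, drugs, survival — in that order) via ``numpy.random.SeedSequence``
so each stage can be regenerated independently and every output is
byte-identical across runs with the same configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .pathway_network import (
    CellLineContext,
    Superpathway,
    merge_pathways,
)
from .screens import DrugScreenInput

__all__ = [
    "SimulationConfig",
    "generate_network",
    "generate_essentiality",
    "generate_contexts_drugs_survival",
    "generate_all",
]

LOSS_EVENTS = ("mutation", "homozygous_deletion", "not_expressed")


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic benchmark.

    Defaults describe a desk-scale screen: 150 proteins across 8
    overlapping pathways, 30 cell lines, hub knockdowns shifted 2 screen
    units more lethal, 5% per-gene loss rate, a 200-patient cohort with a
    3x hazard ratio tied to the planted PPI, and administrative censoring
    at 3000 days (roughly 30% censored at the default hazard).
    """

    n_proteins: int = 150
    n_pathways: int = 8
    pathway_size_range: tuple[int, int] = (12, 30)
    hub_fraction: float = 0.1
    n_cell_lines: int = 30
    essential_hub_bias: float = -2.0
    mutation_rate: float = 0.05
    n_patients: int = 200
    planted_drug_target: str | None = None  # default: first hub gene
    planted_survival_ppi: tuple[str, str] | None = None  # default: top hub edge
    hazard_ratio: float = 3.0
    noise_sd: float = 0.3
    n_hairpins: int = 3
    n_decoy_compounds: int = 4
    baseline_hazard: float = 1.0 / 1500.0  # events per day
    censor_horizon: float = 3000.0  # days
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_proteins", "n_pathways", "n_cell_lines", "n_patients", "n_hairpins"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("hub_fraction", "mutation_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.pathway_size_range
        if lo < 3 or hi < lo:
            raise ValueError("pathway_size_range must satisfy 3 <= lo <= hi")
        if hi > self.n_proteins:
            raise ValueError("pathway size exceeds protein count")

    def substreams(self) -> dict[str, np.random.Generator]:
        """Named per-stage generators fanned out from the master seed."""
        ss = np.random.SeedSequence(self.seed)
        names = ("network", "essentiality", "contexts", "drugs", "survival")
        return {n: np.random.default_rng(c) for n, c in zip(names, ss.spawn(len(names)))}


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


def hub_genes(cfg: SimulationConfig) -> list[str]:
    """Designated hub genes: the first ceil(hub_fraction * n) symbols."""
    k = max(1, int(np.ceil(cfg.hub_fraction * cfg.n_proteins)))
    return _gene_names(cfg.n_proteins)[:k]


def generate_network(cfg: SimulationConfig) -> Superpathway:
    """Union of overlapping preferential-attachment pathway subnetworks.

    Each pathway samples its members with hub genes always eligible (so
    pathways overlap on hubs), builds a Barabasi-Albert graph on them, and
    maps the BA graph's highest-degree positions onto the hub genes. The
    union therefore has hub-heavy degree structure and per-edge pathway
    provenance.
    """
    rng = cfg.substreams()["network"]
    genes = _gene_names(cfg.n_proteins)
    hubs = hub_genes(cfg)
    non_hubs = genes[len(hubs):]
    lo, hi = cfg.pathway_size_range
    pathway_lists = []
    for k in range(cfg.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        n_hub = min(len(hubs), max(1, size // 4))
        chosen_hubs = list(rng.choice(hubs, size=n_hub, replace=False))
        n_rest = size - n_hub
        if n_rest > len(non_hubs):
            raise ValueError("pathway size infeasible for the protein pool")
        rest = list(rng.choice(non_hubs, size=n_rest, replace=False))
        m = 2 if size > 4 else 1
        ba = nx.barabasi_albert_graph(size, m, seed=int(rng.integers(2**31)))
        # highest-degree BA positions become the pathway's hub genes
        by_degree = sorted(ba.nodes(), key=lambda v: (-ba.degree(v), v))
        label = {}
        for pos, gene in zip(by_degree, chosen_hubs + sorted(rest)):
            label[pos] = gene
        edges = [(label[u], label[v]) for u, v in ba.edges()]
        pathway_lists.append((f"pathway{k + 1:02d}", edges))
    return merge_pathways(pathway_lists)


def generate_essentiality(
    cfg: SimulationConfig, sp: Superpathway
) -> pd.DataFrame:
    """Hairpin-level knockdown scores, screen scale (negative = lethal).

    Each gene gets a latent per-cell-line lethality: hub genes draw their
    mean from ``essential_hub_bias`` (more negative), others from 0, both
    with unit gene-to-gene spread; hairpins add ``noise_sd`` measurement
    noise. Returned as a DataFrame with index the hairpin id, a ``gene``
    column, and one column per cell line — the in-memory mirror of a
    GCT 1.2 file (Name = hairpin, Description = gene).
    """
    rng = cfg.substreams()["essentiality"]
    genes = sorted(sp.nodes)
    hubs = set(hub_genes(cfg))
    lines = [f"CL{i:03d}" for i in range(1, cfg.n_cell_lines + 1)]
    gene_mean = {
        g: (cfg.essential_hub_bias if g in hubs else 0.0) + rng.normal(0, 0.5)
        for g in genes
    }
    rows = {}
    gene_col = []
    for g in genes:
        line_mean = gene_mean[g] + rng.normal(0, 0.3, size=len(lines))
        for h in range(1, cfg.n_hairpins + 1):
            rows[f"{g}-sh{h}"] = line_mean + rng.normal(0, cfg.noise_sd, size=len(lines))
            gene_col.append(g)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=lines)
    df.insert(0, "gene", gene_col)
    return df


def _default_planted(cfg: SimulationConfig, sp: Superpathway) -> tuple[str, tuple[str, str]]:
    """Planted drug target = highest-degree hub; planted survival PPI = its
    strongest hub-hub edge, else its first edge."""
    g = sp.to_networkx()
    hubs = [h for h in hub_genes(cfg) if h in g]
    if not hubs:
        raise ValueError("no hub gene present in the generated network")
    target = max(hubs, key=lambda h: (g.degree(h), h))
    nbrs = sorted(g.neighbors(target))
    if not nbrs:
        raise ValueError("planted target has no interactions")
    hub_nbrs = [n for n in nbrs if n in set(hubs)]
    partner = hub_nbrs[0] if hub_nbrs else nbrs[0]
    return target, tuple(sorted((target, partner)))


def generate_contexts_drugs_survival(
    cfg: SimulationConfig,
    sp: Superpathway,
    shrna: pd.DataFrame,
) -> tuple[list[CellLineContext], DrugScreenInput, pd.DataFrame, pd.DataFrame]:
    """Loss contexts, drug screen and patient cohort for the network.

    Returns ``(contexts, drug_screen, patient_mutations, clinical)``:

    * contexts — per cell line, each gene lost independently at
      ``mutation_rate`` with a uniformly drawn event type; all genes
      measured.
    * drug screen — one planted compound whose AUC across cell lines is the
      planted target gene's normalized essentiality plus noise calibrated
      for r ~ 0.7, plus decoy compounds with random AUCs and random target
      genes. Higher AUC = more sensitive, so lethal-target lines are
      sensitive to the planted compound.
    * patients — each patient retains or loses the planted survival PPI
      (one partner hit by a nonsense/frameshift/homozygous-deletion event,
      probability 1/2) on top of sparse random background alterations;
      survival is exponential with hazard ``baseline_hazard`` multiplied by
      ``hazard_ratio`` while the PPI is intact, censored administratively
      at ``censor_horizon`` days.
    """
    streams = cfg.substreams()
    genes = sorted(sp.nodes)
    lines = [c for c in shrna.columns if c != "gene"]

    # contexts -------------------------------------------------------------
    rng = streams["contexts"]
    contexts = []
    for cl in lines:
        lost = {}
        for g in genes:
            if rng.random() < cfg.mutation_rate:
                lost[g] = LOSS_EVENTS[int(rng.integers(len(LOSS_EVENTS)))]
        contexts.append(
            CellLineContext(
                cell_line=cl,
                lost_genes=set(lost),
                measured_genes=set(genes),
            )
        )
        # keep event labels for serialization
        contexts[-1].loss_events = lost  # type: ignore[attr-defined]

    # drug screen ----------------------------------------------------------
    rng = streams["drugs"]
    target_default, ppi_default = _default_planted(cfg, sp)
    target = cfg.planted_drug_target or target_default
    if target not in sp.nodes:
        raise ValueError(f"planted drug target {target!r} absent from network")
    # second-most-lethal collapse of the target's hairpins, negated min-max
    sub = shrna.loc[shrna["gene"] == target, lines]
    collapsed = sub.apply(lambda col: col.nsmallest(2).iloc[-1], axis=0)
    z = (collapsed - collapsed.mean()) / collapsed.std(ddof=0)
    # AUC = -z + noise: more lethal target (negative z) -> higher sensitivity
    noise_scale = np.sqrt(1.0 / 0.7**2 - 1.0)  # population r ~ 0.7
    planted_auc = -z.to_numpy() + rng.normal(0, noise_scale, size=len(lines))
    auc_rows = {"planted-compound": planted_auc}
    targets = {"planted-compound": {target}}
    non_targets = [g for g in genes if g != target]
    for d in range(1, cfg.n_decoy_compounds + 1):
        name = f"decoy-{d:02d}"
        auc_rows[name] = rng.normal(0, 1, size=len(lines))
        targets[name] = {non_targets[int(rng.integers(len(non_targets)))]}
    drug = DrugScreenInput(
        auc=pd.DataFrame.from_dict(auc_rows, orient="index", columns=lines),
        targets=targets,
    )

    # patients -------------------------------------------------------------
    rng = streams["survival"]
    ppi = tuple(cfg.planted_survival_ppi or ppi_default)
    if not set(ppi) <= sp.nodes:
        raise ValueError(f"planted survival PPI {ppi} absent from network")
    disrupting = [
        ("nonsense", "normal"),
        ("frameshift", "normal"),
        ("missense", "homozygous_deletion"),
    ]
    mut_rows = []
    clin_rows = []
    for i in range(1, cfg.n_patients + 1):
        pid = f"PT{i:04d}"
        retains = rng.random() < 0.5
        if not retains:
            partner = ppi[int(rng.integers(2))]
            vc, cs = disrupting[int(rng.integers(len(disrupting)))]
            mut_rows.append((pid, partner, vc, cs))
        # sparse passenger alterations that never touch the planted PPI
        for _ in range(int(rng.poisson(2.0))):
            g = genes[int(rng.integers(len(genes)))]
            if g in ppi:
                continue
            mut_rows.append((pid, g, "missense", "normal"))
        hazard = cfg.baseline_hazard * (cfg.hazard_ratio if retains else 1.0)
        t = rng.exponential(1.0 / hazard)
        event = t <= cfg.censor_horizon
        clin_rows.append((pid, min(t, cfg.censor_horizon), int(event)))
    mutations = pd.DataFrame(
        mut_rows, columns=["patient", "gene", "variant_class", "copy_state"]
    )
    clinical = pd.DataFrame(clin_rows, columns=["patient", "time_days", "event"])
    return contexts, drug, mutations, clinical


def generate_all(cfg: SimulationConfig):
    """Run all three stages; returns (superpathway, shrna, contexts, drug,
    mutations, clinical)."""
    sp = generate_network(cfg)
    shrna = generate_essentiality(cfg, sp)
    contexts, drug, mutations, clinical = generate_contexts_drugs_survival(cfg, sp, shrna)
    return sp, shrna, contexts, drug, mutations, clinical


def planted_choices(cfg: SimulationConfig, sp: Superpathway) -> tuple[str, tuple[str, str]]:
    """The planted drug target and survival PPI actually in effect."""
    target_default, ppi_default = _default_planted(cfg, sp)
    return (
        cfg.planted_drug_target or target_default,
        tuple(cfg.planted_survival_ppi or ppi_default),
    )
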