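"""Synthetic data generators for every pipeline input.

Emulates the data shapes and statistical structure of a dosed-probiotic
study in a three-vessel colon simulator run in triplicate: qPCR cell-count
trajectories (washout model plus endogenous baseline and multiplicative
lognormal noise), overdispersed ASV feature tables with region and
bioreplicate structure and a spiked probiotic ASV, SCFA concentration tables
increasing along the AC -> TC -> DC sequence, and random rooted trees for
phylogenetic diversity.  All generators are deterministic under a fixed
seed; each draws from its own fixed substream so the outputs are independent
of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd
from skbio import TreeNode

from .model import (
    DEFAULT_CHAIN,
    DEFAULT_SCHEDULE,
    DoseEvent,
    FeedingSchedule,
    GrowthParams,
    ReactorChain,
    simulate_with_growth,
)
from .qpcr import QpcrSeries

__all__ = [
    "SynthConfig",
    "QpcrDataset",
    "gen_qpcr_trajectory",
    "gen_feature_table",
    "gen_tree",
    "gen_scfa",
    "gen_all",
]

# fixed substream keys so each generator is reproducible independently
_STREAM_QPCR, _STREAM_TABLE, _STREAM_TREE, _STREAM_SCFA = 11, 12, 13, 14

_GENUS_POOL = (
    "Bacteroides", "Prevotella", "Ruminococcus", "Faecalibacterium", "Blautia",
    "Acidaminococcus", "Megasphaera", "Sutterella", "Escherichia", "Citrobacter",
    "Bifidobacterium", "Akkermansia", "Fusobacterium", "Clostridium", "Roseburia",
    "Dorea", "Coprococcus", "Parabacteroides", "Alistipes", "Dialister",
)

_PHYLUM_OF_GENUS = {
    "Bacteroides": "Bacteroidetes", "Prevotella": "Bacteroidetes",
    "Parabacteroides": "Bacteroidetes", "Alistipes": "Bacteroidetes",
    "Ruminococcus": "Firmicutes", "Faecalibacterium": "Firmicutes",
    "Blautia": "Firmicutes", "Acidaminococcus": "Firmicutes",
    "Megasphaera": "Firmicutes", "Clostridium": "Firmicutes",
    "Roseburia": "Firmicutes", "Dorea": "Firmicutes", "Coprococcus": "Firmicutes",
    "Dialister": "Firmicutes",
    "Sutterella": "Proteobacteria", "Escherichia": "Proteobacteria",
    "Citrobacter": "Proteobacteria",
    "Bifidobacterium": "Actinobacteria",
    "Akkermansia": "Verrucomicrobia",
    "Fusobacterium": "Fusobacteria",
}

PROBIOTIC_ASV_ID = "ASV_probiotic"
PROBIOTIC_LINEAGE = (
    "k__Bacteria; p__Firmicutes; c__Bacilli; o__Lactobacillales; "
    "f__Lactobacillaceae; g__Lacticaseibacillus; s__rhamnosus"
)


@dataclass
class SynthConfig:
    """Study-condition parameters for the generators.

    Defaults describe the emulated study: three bioreplicates, a three-vessel
    AC/TC/DC chain dosed once into the AC at cycle 0 with ~5e6 cells/mL
    (2.5e9 cells into 500 mL), a 31-cycle horizon at three cycles/day,
    endogenous baselines log-uniform in [1.3e3, 8e4] cells/mL, net growth
    1.2 in the AC and 0.9 downstream, and multiplicative lognormal qPCR
    noise with sd 0.1 on the log scale.
    """

    seed: int = 0
    chain: ReactorChain = field(default_factory=lambda: DEFAULT_CHAIN)
    schedule: FeedingSchedule = field(default_factory=lambda: DEFAULT_SCHEDULE)
    dose_compartment: str = "AC"
    dose_cycle: int = 0
    dose_total_cells: float = 2.5e9
    n_cycles: int = 31
    bioreplicates: tuple[str, ...] = ("BR1", "BR2", "BR3")
    growth_multipliers: dict = field(
        default_factory=lambda: {"AC": 1.2, "TC": 0.9, "DC": 0.9}
    )
    qpcr_noise_sd: float = 0.1
    baseline_range: tuple[float, float] = (1.3e3, 8.0e4)
    pre_dose_cycles: tuple[int, ...] = (-3, -2, -1)
    include_mucin: bool = True
    mucin_factor: float = 0.03  # mucosal signal 1-2 log below luminal
    # feature-table parameters
    n_taxa: int = 60
    depth: int = 20000
    samples_per_group: int = 2
    periods: tuple[str, ...] = ("pre", "early-post", "late-post")
    dirichlet_concentration: dict = field(
        default_factory=lambda: {"AC": 0.1, "TC": 1.0, "DC": 1.0}
    )
    phylum_probs: dict = field(
        default_factory=lambda: {
            "Firmicutes": 0.45,
            "Bacteroidetes": 0.35,
            "Proteobacteria": 0.08,
            "Fusobacteria": 0.05,
            "Actinobacteria": 0.04,
            "Verrucomicrobia": 0.03,
        }
    )
    probiotic_spike_weight: float = 0.05  # read fraction in post-dose AC samples
    # SCFA parameters
    scfa_base_means: dict = field(
        default_factory=lambda: {
            "acetic": 800.0,
            "propanoic": 350.0,
            "butanoic": 250.0,
            "pentanoic": 60.0,
            "hexanoic": 20.0,
            "2-methylpropanoic": 40.0,
            "3-methylbutanoic": 35.0,
            "4-methylpentanoic": 10.0,
        }
    )
    scfa_region_factor: dict = field(
        default_factory=lambda: {"AC": 1.0, "TC": 1.4, "DC": 1.8}
    )
    scfa_noise_sd: float = 0.15
    scfa_post_bump: float = 0.1  # extra log-sd in early-post samples
    tree_mean_branch_length: float = 0.1

    @property
    def dose(self) -> DoseEvent:
        return DoseEvent(self.dose_compartment, self.dose_cycle, self.dose_total_cells)


@dataclass
class QpcrDataset:
    """Generated qPCR series plus the noise-free truth and generating parameters."""

    observed: list[QpcrSeries]
    truth: list[QpcrSeries]
    baselines: dict  # (bioreplicate, compartment, phase) -> cells/mL
    growth: dict  # compartment -> multiplier

    def frame(self) -> pd.DataFrame:
        """Long-format observed table, as the qPCR CSV reader expects."""
        rows = []
        for s in self.observed:
            for cyc, val in zip(s.cycles, s.cells_per_ml):
                rows.append(
                    {
                        "sample_id": f"{s.bioreplicate}_{s.compartment}_{s.phase}_c{int(cyc)}",
                        "bioreplicate": s.bioreplicate,
                        "compartment": s.compartment,
                        "phase": s.phase,
                        "cycle": int(cyc),
                        "cells_per_ml": val,
                    }
                )
        return pd.DataFrame(rows)


def gen_qpcr_trajectory(cfg: SynthConfig) -> QpcrDataset:
    """qPCR time series from the growth-extended washout model.

    Truth per (bioreplicate, compartment): model trajectory plus a constant
    endogenous baseline, with baseline-level pre-dose cycles.  Observed
    values multiply the truth by exp(N(0, qpcr_noise_sd)).  Mucosal series
    (optional) scale the luminal signal by ``mucin_factor``.
    """
    rng = np.random.default_rng([cfg.seed, _STREAM_QPCR])
    growth = GrowthParams.from_mapping(cfg.chain, cfg.growth_multipliers)
    traj = simulate_with_growth(cfg.chain, cfg.schedule, cfg.dose, growth, cfg.n_cycles)
    cycles = np.concatenate([np.array(cfg.pre_dose_cycles, dtype=int), traj.cycle_axis])
    lo, hi = cfg.baseline_range
    observed, truth, baselines = [], [], {}
    phases = ["lumen"] + (["mucin"] if cfg.include_mucin else [])
    for br in cfg.bioreplicates:
        for comp in cfg.chain.names:
            signal = traj.series(comp)
            for phase in phases:
                scale = 1.0 if phase == "lumen" else cfg.mucin_factor
                baseline = float(np.exp(rng.uniform(np.log(lo), np.log(hi)))) * scale
                baselines[(br, comp, phase)] = baseline
                clean = np.concatenate(
                    [np.full(len(cfg.pre_dose_cycles), baseline), signal * scale + baseline]
                )
                noise = (
                    np.exp(rng.normal(0.0, cfg.qpcr_noise_sd, size=clean.size))
                    if cfg.qpcr_noise_sd > 0
                    else np.ones(clean.size)
                )
                truth.append(QpcrSeries(br, comp, phase, cycles.copy(), clean))
                observed.append(QpcrSeries(br, comp, phase, cycles.copy(), clean * noise))
    return QpcrDataset(observed, truth, baselines, dict(cfg.growth_multipliers))


def _assign_taxonomy(cfg: SynthConfig, rng: np.random.Generator) -> dict[str, str]:
    phyla = list(cfg.phylum_probs)
    probs = np.array([cfg.phylum_probs[p] for p in phyla], dtype=float)
    probs /= probs.sum()
    taxonomy = {}
    for i in range(cfg.n_taxa):
        phylum = phyla[rng.choice(len(phyla), p=probs)]
        candidates = [g for g in _GENUS_POOL if _PHYLUM_OF_GENUS[g] == phylum]
        genus = candidates[rng.integers(len(candidates))] if candidates else f"Genus{i:03d}"
        taxonomy[f"ASV_{i:04d}"] = (
            f"k__Bacteria; p__{phylum}; c__; o__; f__; g__{genus}; s__"
        )
    taxonomy[PROBIOTIC_ASV_ID] = PROBIOTIC_LINEAGE
    return taxonomy


def gen_feature_table(cfg: SynthConfig):
    """Overdispersed ASV count table with region/bioreplicate structure.

    Per-sample compositions are Dirichlet draws around a bioreplicate-specific
    base composition, with a smaller concentration parameter in the AC (more
    uneven, hence less diverse) than in the TC/DC.  Counts are multinomial at
    the configured depth.  A designated probiotic ASV takes the configured
    read fraction in post-dose samples of the dosed compartment.

    Returns ``(FeatureTable, taxonomy dict)``.
    """
    from .community import FeatureTable  # local import to avoid cycles

    if cfg.n_taxa < 5:
        raise ValueError("n_taxa must be >= 5")
    rng = np.random.default_rng([cfg.seed, _STREAM_TABLE])
    taxonomy = _assign_taxonomy(cfg, rng)
    asv_ids = [f"ASV_{i:04d}" for i in range(cfg.n_taxa)] + [PROBIOTIC_ASV_ID]
    counts = {}
    meta = {}
    for br in cfg.bioreplicates:
        base = rng.dirichlet(np.full(cfg.n_taxa, 2.0))
        for region in cfg.chain.names:
            conc = cfg.dirichlet_concentration.get(region, 1.0)
            for period in cfg.periods:
                for rep in range(cfg.samples_per_group):
                    sid = f"{br}_{region}_{period}_r{rep}"
                    p = rng.dirichlet(np.maximum(conc * cfg.n_taxa * base, 1e-6))
                    spike = (
                        cfg.probiotic_spike_weight
                        if (period != "pre" and region == cfg.dose_compartment)
                        else 0.0
                    )
                    full = np.concatenate([(1.0 - spike) * p, [spike]])
                    counts[sid] = rng.multinomial(cfg.depth, full)
                    meta[sid] = {"bioreplicate": br, "region": region, "period": period}
    counts_df = pd.DataFrame(counts, index=asv_ids)
    meta_df = pd.DataFrame.from_dict(meta, orient="index")
    meta_df.index.name = "sample"
    return FeatureTable(counts_df, meta_df), taxonomy


def gen_tree(taxa: list[str], seed: int, mean_branch_length: float = 0.1) -> TreeNode:
    """Random rooted binary tree over ``taxa`` with exponential branch lengths.

    Built by repeatedly joining two uniformly chosen subtrees until one
    remains, so ``n`` taxa give exactly ``n - 1`` internal nodes and
    ``2n - 2`` branches with expected total length ``(2n - 2) * mean``.
    """
    if len(taxa) < 2:
        raise ValueError("need >= 2 taxa to build a tree")
    if len(set(taxa)) != len(taxa):
        raise ValueError("taxon ids must be unique")
    rng = np.random.default_rng([seed, _STREAM_TREE])
    nodes = [str(t) for t in taxa]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b1, b2 = rng.exponential(mean_branch_length, size=2)
        merged = f"({nodes[i]}:{b1:.10g},{nodes[j]}:{b2:.10g})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return TreeNode.read(StringIO(nodes[0] + ";"), convert_underscores=False)


def gen_scfa(cfg: SynthConfig, sample_metadata: pd.DataFrame | None = None):
    """SCFA concentration table (samples x acids, ppm) with the regional trend.

    Concentrations are region mean x lognormal noise; region means increase
    along the chain (AC < TC < DC) for every acid via the region factor.
    Early-post samples get extra log-scale spread to emulate a transient
    post-dose perturbation.  If ``sample_metadata`` is omitted, the same
    sample scheme as :func:`gen_feature_table` is used.

    Returns ``(scfa DataFrame, metadata DataFrame)``.
    """
    for acid, mean in cfg.scfa_base_means.items():
        if mean < 0:
            raise ValueError(f"negative mean for {acid}")
    factors = [cfg.scfa_region_factor.get(r, 1.0) for r in cfg.chain.names]
    if any(b < a for a, b in zip(factors, factors[1:])):
        raise ValueError("region factors must be non-decreasing along the chain")
    rng = np.random.default_rng([cfg.seed, _STREAM_SCFA])
    if sample_metadata is None:
        rows = {}
        for br in cfg.bioreplicates:
            for region in cfg.chain.names:
                for period in cfg.periods:
                    for rep in range(cfg.samples_per_group):
                        rows[f"{br}_{region}_{period}_r{rep}"] = {
                            "bioreplicate": br,
                            "region": region,
                            "period": period,
                        }
        sample_metadata = pd.DataFrame.from_dict(rows, orient="index")
        sample_metadata.index.name = "sample"
    acids = list(cfg.scfa_base_means)
    data = {}
    for sid, row in sample_metadata.iterrows():
        factor = cfg.scfa_region_factor.get(row["region"], 1.0)
        sd = cfg.scfa_noise_sd + (
            cfg.scfa_post_bump if row.get("period") == "early-post" else 0.0
        )
        noise = np.exp(rng.normal(0.0, sd, size=len(acids))) if sd > 0 else np.ones(len(acids))
        data[sid] = {
            acid: cfg.scfa_base_means[acid] * factor * n for acid, n in zip(acids, noise)
        }
    scfa = pd.DataFrame.from_dict(data, orient="index")[acids]
    scfa.index.name = "sample"
    return scfa, sample_metadata


def gen_all(cfg: SynthConfig):
    """Generate the complete input bundle for an end-to-end run.

    Returns a dict with keys ``qpcr`` (QpcrDataset), ``table`` (FeatureTable),
    ``taxonomy``, ``tree`` and ``scfa``.
    """
    qpcr = gen_qpcr_trajectory(cfg)
    table, taxonomy = gen_feature_table(cfg)
    tree = gen_tree(table.asv_ids, cfg.seed, cfg.tree_mean_branch_length)
    scfa, _ = gen_scfa(cfg, table.metadata)
    return {"qpcr": qpcr, "table": table, "taxonomy": taxonomy, "tree": tree, "scfa": scfa}
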