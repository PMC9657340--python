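"""Readers, writers, configuration handling and the top-level pipeline.

Interchange formats are plain text: TSV feature tables (ASV rows, sample
columns), two-column taxonomy TSV, newick trees, long-format qPCR and SCFA
CSVs, TSV sample metadata, YAML run configuration and a JSON report.
Numbers are serialised with 12 significant digits so write/read round-trips
are stable.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

from . import community, engraftment, qpcr
from .model import DoseEvent, FeedingSchedule, ReactorChain, predict_no_growth
from .synth import SynthConfig, gen_all

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_newick",
    "write_newick",
    "read_metadata",
    "write_metadata",
    "read_qpcr",
    "write_qpcr",
    "read_scfa",
    "write_scfa",
    "write_trajectory",
    "RunConfig",
    "load_config",
    "run_pipeline",
    "write_synth_fixtures",
]

logger = logging.getLogger("gutwash")

SIG_DIGITS = 12


def _round_sig(x: float) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return float(f"{x:.{SIG_DIGITS}g}")


def _jsonify(obj):
    """Recursively make an object JSON-serialisable with stable float text."""
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if math.isnan(v) else _round_sig(v)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.to_dict(orient="records"))
    return obj


def write_json_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(_jsonify(report), indent=2, sort_keys=True) + "\n"
    )


# ---------------------------------------------------------------- tables ---

def read_feature_table(path: str | Path, metadata: pd.DataFrame | None = None) -> community.FeatureTable:
    """Read a TSV feature table: first column ASV ids, header row sample ids.

    Counts must be non-negative integers; malformed cells are reported with
    their ASV/sample coordinates.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    if not header:
        raise ValueError(f"empty feature table: {path}")
    samples = header.split("\t")[1:]
    if len(set(samples)) != len(samples):
        dupes = sorted({s for s in samples if samples.count(s) > 1})
        raise ValueError(f"duplicate sample columns in {path}: {dupes}")
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty feature table: {path}") from exc
    if frame.index.duplicated().any():
        dupes = sorted(set(frame.index[frame.index.duplicated()]))
        raise ValueError(f"duplicate ASV ids in {path}: {dupes}")
    frame.index.name = None
    for sample in frame.columns:
        col = pd.to_numeric(frame[sample], errors="coerce")
        bad = frame.index[col.isna()]
        if len(bad):
            raise ValueError(f"non-numeric count at ASV {bad[0]!r}, sample {sample!r}")
        non_int = frame.index[(col % 1) != 0]
        if len(non_int):
            raise ValueError(f"non-integer count at ASV {non_int[0]!r}, sample {sample!r}")
        neg = frame.index[col < 0]
        if len(neg):
            raise ValueError(f"negative count at ASV {neg[0]!r}, sample {sample!r}")
    counts = frame.astype(int)
    return community.FeatureTable(
        counts, metadata if metadata is not None else pd.DataFrame()
    )


def write_feature_table(table: community.FeatureTable, path: str | Path) -> None:
    table.counts.rename_axis("asv_id").to_csv(path, sep="\t")


def read_taxonomy(path: str | Path) -> dict[str, str]:
    """Two-column TSV (ASV id, lineage string) -> dict."""
    frame = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if frame.shape[1] < 2:
        raise ValueError(f"taxonomy file needs two columns: {path}")
    return dict(zip(frame.iloc[:, 0], frame.iloc[:, 1].fillna("")))


def write_taxonomy(taxonomy: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"asv_id": list(taxonomy), "lineage": list(taxonomy.values())}
    ).to_csv(path, sep="\t", index=False)


def read_newick(path: str | Path, expected_tips: set[str] | None = None) -> TreeNode:
    """Parse a rooted newick tree; branch lengths default to 0 with a warning."""
    tree = TreeNode.read(str(path), convert_underscores=False)
    missing_lengths = [n.name for n in tree.traverse(include_self=False) if n.length is None]
    if missing_lengths:
        warnings.warn(f"{len(missing_lengths)} branches without lengths set to 0")
        for node in tree.traverse(include_self=False):
            if node.length is None:
                node.length = 0.0
    if expected_tips is not None:
        tips = {t.name for t in tree.tips()}
        extra = tips - expected_tips
        if extra:
            warnings.warn(f"tree tips absent from feature table: {sorted(extra)}")
    return tree


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path))


def read_metadata(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if frame.index.duplicated().any():
        raise ValueError(f"duplicate sample ids in metadata: {path}")
    return frame


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.rename_axis("sample").to_csv(path, sep="\t")


def read_qpcr(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"bioreplicate", "compartment", "phase", "cycle"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    return frame


def write_qpcr(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


def read_scfa(path: str | Path) -> pd.DataFrame:
    """Long-format SCFA CSV (sample, acid, concentration_ppm) -> samples x acids."""
    frame = pd.read_csv(path)
    required = {"sample", "acid", "concentration_ppm"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"SCFA table missing columns: {sorted(missing)}")
    if (frame["concentration_ppm"] < 0).any():
        raise ValueError("SCFA concentrations must be >= 0")
    wide = frame.pivot_table(
        index="sample", columns="acid", values="concentration_ppm", sort=False
    )
    wide.columns.name = None
    return wide


def write_scfa(scfa: pd.DataFrame, path: str | Path) -> None:
    long = scfa.rename_axis("sample").reset_index().melt(
        id_vars="sample", var_name="acid", value_name="concentration_ppm"
    )
    long.to_csv(path, index=False)


def write_trajectory(traj, path: str | Path) -> None:
    """Long-format TSV: cycle, compartment, concentration, cumulative waste."""
    frame = traj.to_frame()
    for col in ("concentration_cells_per_ml", "cumulative_waste_cells"):
        frame[col] = frame[col].map(_round_sig)
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- config ---

_TOP_KEYS = {"seed", "inputs", "reactor", "dose", "growth_multipliers", "analysis", "outdir"}
_INPUT_KEYS = {"qpcr", "feature_table", "taxonomy", "tree", "metadata", "scfa"}
_REACTOR_KEYS = {"compartments", "transfer_volume_ml", "cycles_per_day", "n_cycles", "transit_ordering"}
_DOSE_KEYS = {"compartment", "cycle", "total_cells"}
_ANALYSIS_KEYS = {
    "window", "factor", "baseline_method", "shannon_base",
    "scfa_alpha", "scfa_group_a", "scfa_group_b", "n_bootstrap", "bootstrap_seed",
}


def _check_keys(block: dict, allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown config keys in {where}: {sorted(unknown)}")


@dataclass
class RunConfig:
    """Resolved run configuration (paths, geometry, analysis options)."""

    seed: int = 0
    inputs: dict = field(default_factory=dict)
    chain: ReactorChain = None  # type: ignore[assignment]
    schedule: FeedingSchedule = None  # type: ignore[assignment]
    n_cycles: int = 31
    transit_ordering: str = "simultaneous"
    dose: DoseEvent = None  # type: ignore[assignment]
    growth_multipliers: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    outdir: Path = Path(".")


_ANALYSIS_DEFAULTS = {
    "window": 6,
    "factor": 2.0,
    "baseline_method": "mean",
    "shannon_base": math.e,
    "scfa_alpha": 0.05,
    "scfa_group_a": "pre",
    "scfa_group_b": "late-post",
    "n_bootstrap": 0,
    "bootstrap_seed": engraftment.DEFAULT_BOOTSTRAP_SEED,
}


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys are errors."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    _check_keys(raw, _TOP_KEYS, "top level")
    inputs = raw.get("inputs", {})
    _check_keys(inputs, _INPUT_KEYS, "inputs")
    base = Path(path).parent
    resolved_inputs = {}
    for key, p in inputs.items():
        full = (base / p) if not Path(p).is_absolute() else Path(p)
        if not full.exists():
            raise FileNotFoundError(f"input {key!r} does not exist: {full}")
        resolved_inputs[key] = full

    reactor = raw.get("reactor", {})
    _check_keys(reactor, _REACTOR_KEYS, "reactor")
    comp_spec = reactor.get(
        "compartments",
        [{"name": "AC", "volume_ml": 500.0}, {"name": "TC", "volume_ml": 800.0},
         {"name": "DC", "volume_ml": 600.0}],
    )
    chain = ReactorChain.from_volumes(
        [(c["name"], float(c["volume_ml"])) for c in comp_spec]
    )
    schedule = FeedingSchedule(
        transfer_volume=float(reactor.get("transfer_volume_ml", 140.0)),
        cycles_per_day=int(reactor.get("cycles_per_day", 3)),
    )
    dose_block = raw.get("dose", {})
    _check_keys(dose_block, _DOSE_KEYS, "dose")
    dose = DoseEvent(
        compartment=dose_block.get("compartment", chain.names[0]),
        cycle=int(dose_block.get("cycle", 0)),
        total_cells=float(dose_block.get("total_cells", 2.5e9)),
    )
    analysis_block = raw.get("analysis", {})
    _check_keys(analysis_block, _ANALYSIS_KEYS, "analysis")
    analysis = {**_ANALYSIS_DEFAULTS, **analysis_block}
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        inputs=resolved_inputs,
        chain=chain,
        schedule=schedule,
        n_cycles=int(reactor.get("n_cycles", 31)),
        transit_ordering=str(reactor.get("transit_ordering", "simultaneous")),
        dose=dose,
        growth_multipliers=raw.get("growth_multipliers", {}) or {},
        analysis=analysis,
        outdir=Path(raw.get("outdir", ".")),
    )


# -------------------------------------------------------------- pipeline ---

def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute quantify -> predict -> engraft -> diversity -> scfa.

    Stages whose inputs are absent from the configuration are skipped and
    logged.  Writes ``report.json`` plus flat TSV tables to ``outdir`` and
    returns the report dict.  The report carries the seed and every resolved
    analysis default, and contains no timestamps, so repeat runs on the same
    inputs are byte-identical.
    """
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if "qpcr" not in config.inputs:
        raise ValueError("config must provide at least the qpcr input")

    report: dict = {
        "gutwash_version": _pkg_version("gutwash"),
        "seed": config.seed,
        "settings": {
            "chain": {n: v for n, v in zip(config.chain.names, config.chain.volumes)},
            "transfer_volume_ml": config.schedule.transfer_volume,
            "cycles_per_day": config.schedule.cycles_per_day,
            "n_cycles": config.n_cycles,
            "transit_ordering": config.transit_ordering,
            "dose": {
                "compartment": config.dose.compartment,
                "cycle": config.dose.cycle,
                "total_cells": config.dose.total_cells,
            },
            "analysis": dict(config.analysis),
        },
        "stages": {},
    }

    # --- quantify: baselines and baseline-subtracted concentration series
    logger.info("stage quantify: %s", config.inputs["qpcr"])
    qpcr_frame = read_qpcr(config.inputs["qpcr"])
    series_list = qpcr.series_from_frame(qpcr_frame)
    adjusted: list[qpcr.QpcrSeries] = []
    baselines = {}
    for s in series_list:
        try:
            s.baseline = qpcr.estimate_baseline(
                s, config.dose.cycle, config.analysis["baseline_method"]
            )
        except ValueError:
            logger.warning("no pre-dose samples for %s; baseline set to 0", s.key())
            s.baseline = 0.0
        baselines["/".join(s.key())] = s.baseline
        adjusted.append(qpcr.baseline_subtract(s, config.dose.cycle))
    cells_rows = []
    for s in adjusted:
        for cyc, val in zip(s.cycles, s.cells_per_ml):
            cells_rows.append(
                {
                    "bioreplicate": s.bioreplicate,
                    "compartment": s.compartment,
                    "phase": s.phase,
                    "cycle": int(cyc),
                    "cells_per_ml": _round_sig(float(val)),
                }
            )
    pd.DataFrame(cells_rows).to_csv(outdir / "cells.csv", index=False)
    report["stages"]["quantify"] = {
        "n_series": len(adjusted),
        "baselines_cells_per_ml": baselines,
        "clamped_points": {"/".join(s.key()): s.n_clamped for s in adjusted},
    }

    # --- predict: no-growth washout trajectory
    traj = predict_no_growth(
        config.chain, config.schedule, config.dose, config.n_cycles,
        ordering=config.transit_ordering,
    )
    write_trajectory(traj, outdir / "trajectory.tsv")
    report["stages"]["predict"] = {
        "final_concentrations_cells_per_ml": {
            n: traj.series(n)[-1] for n in config.chain.names
        },
        "cumulative_waste_cells": traj.cumulative_waste_cells[-1],
    }

    # --- engraft
    by_br: dict[str, list[qpcr.QpcrSeries]] = {}
    for s in adjusted:
        by_br.setdefault(s.bioreplicate, []).append(s)
    engraft_reports = []
    for br in sorted(by_br):
        engraft_reports.append(
            engraftment.build_report(
                br, by_br[br], config.chain, config.schedule, config.dose,
                window=int(config.analysis["window"]),
                factor=float(config.analysis["factor"]),
                n_bootstrap=int(config.analysis["n_bootstrap"]),
                seed=int(config.analysis["bootstrap_seed"]),
            ).to_dict()
        )
    report["stages"]["engraft"] = {"bioreplicates": engraft_reports}

    # --- diversity
    have_diversity = {"feature_table", "taxonomy", "metadata"} <= set(config.inputs)
    if have_diversity:
        meta = read_metadata(config.inputs["metadata"])
        table = read_feature_table(config.inputs["feature_table"], metadata=meta)
        taxonomy = read_taxonomy(config.inputs["taxonomy"])
        tree = None
        if "tree" in config.inputs:
            tree = read_newick(config.inputs["tree"], expected_tips=set(table.asv_ids))
        targets = community.find_probiotic_asvs(taxonomy)
        stripped = community.remove_probiotic_asvs(table, targets)
        alpha = community.alpha_diversity_frame(
            stripped, tree=tree, base=float(config.analysis["shannon_base"])
        )
        alpha.to_csv(outdir / "alpha.tsv", sep="\t")
        tests = {}
        metrics = ["shannon", "richness"] + (["faith_pd"] if tree is not None else [])
        for metric in metrics:
            try:
                res = community.alpha_group_test(
                    alpha[metric].to_numpy(), alpha["region"].to_numpy()
                )
                tests[metric] = {
                    "f": res.f_statistic,
                    "p": res.p_value,
                    "df": [res.df_between, res.df_within],
                    "pairwise": res.pairwise.to_dict(orient="records"),
                }
            except ValueError as exc:
                tests[metric] = {"error": str(exc)}
        phyla = community.aggregate_by_rank(stripped, taxonomy, "phylum")
        ratio = community.fb_ratio(stripped, taxonomy)
        ratio.to_frame().rename_axis("sample").to_csv(outdir / "fb_ratio.tsv", sep="\t")
        report["stages"]["diversity"] = {
            "probiotic_asvs_removed": sorted(targets & set(table.asv_ids)),
            "alpha_by_region_anova": tests,
            "mean_alpha_by_region": {
                m: alpha.groupby("region")[m].mean().to_dict() for m in metrics
            },
            "phylum_mean_relative_abundance": phyla.mean(axis=1).sort_values(
                ascending=False
            ).to_dict(),
            "fb_ratio_median": float(ratio.replace([np.inf, -np.inf], np.nan).median()),
        }
    else:
        logger.info("diversity stage skipped: feature table inputs not configured")
        report["stages"]["diversity"] = {"skipped": True}

    # --- scfa
    if "scfa" in config.inputs and have_diversity:
        scfa = read_scfa(config.inputs["scfa"])
        genus = community.aggregate_by_rank(stripped, taxonomy, "genus")
        corr = community.scfa_taxon_correlation(scfa, genus)
        corr.to_csv(outdir / "scfa_correlations.tsv", sep="\t", index=False)
        tests_frame, n_sig = community.pairwise_scfa_tests(
            scfa,
            meta,
            group_a=str(config.analysis["scfa_group_a"]),
            group_b=str(config.analysis["scfa_group_b"]),
            alpha=float(config.analysis["scfa_alpha"]),
        )
        tests_frame.to_csv(outdir / "scfa_tests.tsv", sep="\t", index=False)
        report["stages"]["scfa"] = {
            "n_pairs_tested": int(tests_frame["p"].notna().sum()),
            "n_significant": n_sig,
            "n_correlations": int(corr["r"].notna().sum()),
            "strongest_correlations": corr.dropna(subset=["r"])
            .reindex(corr["r"].abs().sort_values(ascending=False).index)
            .head(5)
            .to_dict(orient="records"),
        }
    else:
        logger.info("scfa stage skipped: scfa/feature inputs not configured")
        report["stages"]["scfa"] = {"skipped": True}

    write_json_report(report, outdir / "report.json")
    return report


def write_synth_fixtures(cfg: SynthConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate the full synthetic bundle and write every interchange file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = gen_all(cfg)
    paths = {
        "qpcr": outdir / "qpcr.csv",
        "feature_table": outdir / "table.tsv",
        "taxonomy": outdir / "tax.tsv",
        "tree": outdir / "tree.nwk",
        "metadata": outdir / "meta.tsv",
        "scfa": outdir / "scfa.csv",
    }
    frame = bundle["qpcr"].frame()
    frame["cells_per_ml"] = frame["cells_per_ml"].map(_round_sig)
    write_qpcr(frame, paths["qpcr"])
    write_feature_table(bundle["table"], paths["feature_table"])
    write_taxonomy(bundle["taxonomy"], paths["taxonomy"])
    write_newick(bundle["tree"], paths["tree"])
    write_metadata(bundle["table"].metadata, paths["metadata"])
    scfa = bundle["scfa"].copy()
    scfa[scfa.columns] = scfa[scfa.columns].map(_round_sig)
    write_scfa(scfa, paths["scfa"])
    return paths
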