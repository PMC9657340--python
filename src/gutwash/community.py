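"""Community structure and metabolite statistics for ASV feature tables.

Covers the 16S/SCFA side of the analysis: removal of the dosed organism's
ASVs before diversity calculations, alpha-diversity metrics (Shannon in
nats, observed richness, Faith's phylogenetic diversity), one-way ANOVA with
Tukey HSD group comparisons, taxonomic aggregation from Greengenes-style
lineage strings, the Firmicutes/Bacteroidetes ratio, Pearson correlations
between SCFA concentrations and genus-level relative abundances, and
stratified pre/post Welch tests of single-SCFA differences.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "FeatureTable",
    "RANKS",
    "parse_lineage",
    "remove_probiotic_asvs",
    "find_probiotic_asvs",
    "shannon",
    "richness",
    "faith_pd",
    "alpha_diversity_frame",
    "AlphaGroupTest",
    "alpha_group_test",
    "aggregate_by_rank",
    "fb_ratio",
    "scfa_taxon_correlation",
    "pairwise_scfa_tests",
    "SCFA_ACIDS",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")

#: Acids quantified by the GC-MS panel (concentrations in ppm).
SCFA_ACIDS = (
    "acetic",
    "propanoic",
    "butanoic",
    "pentanoic",
    "hexanoic",
    "2-methylpropanoic",
    "3-methylbutanoic",
    "4-methylpentanoic",
)


@dataclass
class FeatureTable:
    """ASV count matrix (ASVs x samples) with per-sample metadata.

    ``counts`` is indexed by ASV id with sample-id columns; ``metadata`` is
    indexed by sample id with at least ``bioreplicate``, ``region`` and
    ``period`` columns (period labels time relative to the dose, e.g.
    pre / early-post / late-post).
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.index.duplicated().any():
            raise ValueError("ASV ids must be unique")
        if self.counts.columns.duplicated().any():
            raise ValueError("sample ids must be unique")
        if len(self.metadata):
            missing = set(self.counts.columns) - set(self.metadata.index)
            if missing:
                raise ValueError(f"samples missing metadata: {sorted(missing)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.index)

    def depth(self) -> pd.Series:
        """Total reads per sample."""
        return self.counts.sum(axis=0)


def parse_lineage(lineage: str) -> dict[str, str]:
    """Parse a Greengenes-style lineage string into rank -> name.

    Accepts e.g. ``"k__Bacteria; p__Firmicutes; c__; o__"``; empty ranks are
    omitted from the result, missing trailing ranks are allowed.
    """
    out: dict[str, str] = {}
    for token in str(lineage).split(";"):
        token = token.strip()
        if not token:
            continue
        for rank, prefix in zip(RANKS, _PREFIXES):
            if token.startswith(prefix):
                name = token[len(prefix):].strip()
                if name:
                    out[rank] = name
                break
    return out


def find_probiotic_asvs(
    taxonomy: dict[str, str],
    genera: tuple[str, ...] = ("Lactobacillus", "Lacticaseibacillus"),
) -> set[str]:
    """ASV ids whose lineage genus matches the dosed organism's genus names."""
    hits = set()
    for asv, lineage in taxonomy.items():
        genus = parse_lineage(lineage).get("genus", "")
        if genus in genera:
            hits.add(asv)
    return hits


def remove_probiotic_asvs(table: FeatureTable, target_asvs: set[str]) -> FeatureTable:
    """Drop the dosed organism's ASVs before diversity calculations.

    The dosed ASVs would trivially inflate post-dose diversity, so they are
    excluded; other counts are untouched.  Removed read totals per sample are
    attached as ``removed_reads`` on the returned table's metadata copy.
    Unknown ids are ignored with a warning.
    """
    unknown = set(target_asvs) - set(table.counts.index)
    if unknown:
        warnings.warn(f"target ASVs not in table (ignored): {sorted(unknown)}")
    present = sorted(set(target_asvs) & set(table.counts.index))
    removed = table.counts.loc[present].sum(axis=0)
    kept = table.counts.drop(index=present)
    meta = table.metadata.copy()
    if len(meta):
        meta["removed_reads"] = removed.reindex(meta.index).fillna(0).astype(int)
    out = FeatureTable(kept, meta)
    return out


def shannon(counts: np.ndarray, base: float = math.e) -> float:
    """Shannon diversity H = -sum p_i log p_i over positive proportions.

    Natural log by default (nats); pass ``base=2`` for bits.  Zero for a
    single taxon, log(S) for S equally abundant taxa.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("all-zero count vector: diversity undefined")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum() / math.log(base))


def richness(counts: np.ndarray) -> int:
    """Observed richness: number of taxa with a positive count."""
    counts = np.asarray(counts, dtype=float)
    return int(np.count_nonzero(counts > 0))


def faith_pd(tree: TreeNode, present: set[str]) -> float:
    """Faith's phylogenetic diversity of the taxa in ``present``.

    Total branch length of the minimal rooted subtree connecting the present
    tips to the root (root-inclusive).  Empty set gives 0 with a warning;
    a tip absent from the tree is an error.
    """
    tips = {t.name for t in tree.tips()}
    unknown = set(present) - tips
    if unknown:
        raise ValueError(f"tips not in tree: {sorted(unknown)}")
    if not present:
        warnings.warn("empty taxon set: Faith's PD is 0")
        return 0.0
    taxa = sorted(tips)
    counts = np.array([1 if t in present else 0 for t in taxa])
    return float(_skbio_faith_pd(counts, taxa=taxa, tree=tree))


def alpha_diversity_frame(
    table: FeatureTable,
    tree: TreeNode | None = None,
    base: float = math.e,
) -> pd.DataFrame:
    """Per-sample Shannon, richness, sequencing depth and (optionally) Faith's PD."""
    rows = {}
    for sample in table.sample_ids:
        counts = table.counts[sample].to_numpy()
        row = {
            "shannon": shannon(counts, base=base),
            "richness": richness(counts),
            "depth": int(counts.sum()),
        }
        if tree is not None:
            present = {a for a, c in zip(table.asv_ids, counts) if c > 0}
            row["faith_pd"] = faith_pd(tree, present)
        rows[sample] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "sample"
    if len(table.metadata):
        frame = frame.join(table.metadata)
    return frame


@dataclass
class AlphaGroupTest:
    """One-way ANOVA with Tukey-Kramer pairwise comparisons."""

    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    pairwise: pd.DataFrame  # columns: group1, group2, meandiff, p_adj
    excluded_groups: list[str]


def alpha_group_test(values: np.ndarray, groups: np.ndarray) -> AlphaGroupTest:
    """Test an alpha-diversity metric for differences among groups.

    One-way ANOVA F-test across groups with >= 2 samples (smaller groups are
    excluded with a warning), followed by Tukey HSD (Tukey-Kramer for
    unbalanced groups) adjusted pairwise p-values.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must align")
    labels, counts = np.unique(groups, return_counts=True)
    excluded = [str(l) for l, c in zip(labels, counts) if c < 2]
    if excluded:
        warnings.warn(f"groups with < 2 samples excluded: {excluded}")
        keep = ~np.isin(groups, excluded)
        values, groups = values[keep], groups[keep]
        labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups with >= 2 samples each")
    by_group = [values[groups == l] for l in labels]
    if all(np.ptp(v) == 0 for v in by_group) and np.ptp(values) == 0:
        raise ValueError("zero variance everywhere: ANOVA degenerate")
    f_stat, p = stats.f_oneway(*by_group)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tukey = pairwise_tukeyhsd(values, groups)
    summary = pd.DataFrame(
        tukey.summary().data[1:], columns=[str(c) for c in tukey.summary().data[0]]
    )
    pairwise = summary[["group1", "group2", "meandiff", "p-adj"]].rename(
        columns={"p-adj": "p_adj"}
    )
    return AlphaGroupTest(
        f_statistic=float(f_stat),
        p_value=float(p),
        df_between=len(labels) - 1,
        df_within=int(values.size - len(labels)),
        pairwise=pairwise,
        excluded_groups=excluded,
    )


def aggregate_by_rank(
    table: FeatureTable, taxonomy: dict[str, str], rank: str
) -> pd.DataFrame:
    """Relative abundances summed at a taxonomic rank (taxa x samples).

    ASVs with no assignment at ``rank`` pool into ``"unclassified"``.  Each
    sample column is normalised to proportions summing to 1.
    """
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}")
    depth = table.depth()
    if (depth <= 0).any():
        empty = list(depth.index[depth <= 0])
        raise ValueError(f"samples with zero reads cannot be normalised: {empty}")
    labels = [
        parse_lineage(taxonomy.get(asv, "")).get(rank, "unclassified") or "unclassified"
        for asv in table.asv_ids
    ]
    summed = table.counts.groupby(pd.Index(labels, name=rank)).sum()
    return summed / depth


def fb_ratio(table: FeatureTable, taxonomy: dict[str, str]) -> pd.Series:
    """Firmicutes/Bacteroidetes abundance ratio per sample.

    A coarse community descriptor; invariant to sequencing depth.  Samples
    with no Bacteroidetes reads give ``inf`` (flagged by the caller via
    ``np.isinf``); samples with neither phylum give ``NaN``.
    """
    phyla = aggregate_by_rank(table, taxonomy, "phylum")
    firmicutes = phyla.loc["Firmicutes"] if "Firmicutes" in phyla.index else 0.0
    bacteroidetes = phyla.loc["Bacteroidetes"] if "Bacteroidetes" in phyla.index else 0.0
    f = pd.Series(firmicutes, index=phyla.columns, dtype=float)
    b = pd.Series(bacteroidetes, index=phyla.columns, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = f / b
    ratio[(f == 0) & (b == 0)] = np.nan
    ratio.name = "fb_ratio"
    return ratio


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def scfa_taxon_correlation(
    scfa: pd.DataFrame, taxa: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation of each SCFA with each taxon's relative abundance.

    ``scfa`` is samples x acids (ppm); ``taxa`` is taxa x samples (genus-level
    relative abundance).  Returns a long table with product-moment r, the
    two-sided t-distribution p-value (n-2 df) and significance stars at
    0.05 / 0.01 / 0.001.  Pairs with fewer than 3 shared samples or zero
    variance are reported with missing r.
    """
    shared = [s for s in scfa.index if s in taxa.columns]
    rows = []
    for acid in scfa.columns:
        for taxon in taxa.index:
            x = scfa.loc[shared, acid].to_numpy(dtype=float)
            y = taxa.loc[taxon, shared].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            r = p = np.nan
            if ok.sum() >= 3 and np.ptp(x[ok]) > 0 and np.ptp(y[ok]) > 0:
                r, p = stats.pearsonr(x[ok], y[ok])
            rows.append(
                {
                    "acid": acid,
                    "taxon": taxon,
                    "n": int(ok.sum()),
                    "r": float(r) if np.isfinite(r) else np.nan,
                    "p": float(p) if np.isfinite(p) else np.nan,
                    "stars": _stars(p) if np.isfinite(p) else "",
                }
            )
    return pd.DataFrame(rows)


def pairwise_scfa_tests(
    scfa: pd.DataFrame,
    metadata: pd.DataFrame,
    group_col: str = "period",
    group_a: str = "pre",
    group_b: str = "late-post",
    strata_cols: tuple[str, ...] = ("bioreplicate", "region"),
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, int]:
    """Welch tests of single-SCFA differences between two periods, per stratum.

    Strata are every combination of ``strata_cols`` x acid.  Each stratum with
    >= 2 samples per group gets an unequal-variance two-sample t-test; smaller
    strata are skipped with a warning and reported with missing p.  Returns
    the per-stratum table and the count of strata with p < ``alpha``
    (no multiplicity correction, mirroring raw significant-pair counts).
    """
    meta = metadata.loc[[s for s in scfa.index if s in metadata.index]]
    rows = []
    skipped = 0
    for keys, grp in meta.groupby(list(strata_cols), sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        a_ids = grp.index[grp[group_col] == group_a]
        b_ids = grp.index[grp[group_col] == group_b]
        for acid in scfa.columns:
            a = scfa.loc[a_ids, acid].dropna().to_numpy(dtype=float)
            b = scfa.loc[b_ids, acid].dropna().to_numpy(dtype=float)
            row = dict(zip(strata_cols, keys))
            row["acid"] = acid
            row["n_a"], row["n_b"] = len(a), len(b)
            if len(a) >= 2 and len(b) >= 2:
                t, p = stats.ttest_ind(a, b, equal_var=False)
                row["t"], row["p"] = float(t), float(p)
                row["significant"] = bool(p < alpha)
            else:
                skipped += 1
                row["t"], row["p"], row["significant"] = np.nan, np.nan, False
            rows.append(row)
    if skipped:
        warnings.warn(f"{skipped} strata skipped (need >= 2 samples per group)")
    frame = pd.DataFrame(rows)
    n_significant = int(frame["significant"].sum()) if len(frame) else 0
    return frame, n_significant
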