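"""Genome-wide CNV landscape summaries.

All operations take the per-fragment call table (fragment_id, genotype,
class) together with fragment positions (fragment_id, chromosome,
phys_start). A fragment is "variant" when it carries a call in at least one
genotype. Windows are half-open and fragments are assigned to windows by
their start coordinate, so no fragment is double-counted.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats


def variant_fragments(calls: pd.DataFrame) -> pd.Series:
    """Number of genotypes sharing each called fragment."""
    return calls.groupby("fragment_id")["genotype"].nunique()


def frequency_spectrum(calls: pd.DataFrame, n_genotypes: int) -> pd.DataFrame:
    """Sharing spectrum: how many variant fragments occur in 1..n genotypes.

    Returns a DataFrame (n_genotypes_sharing, n_variants, fraction); the
    singleton fraction is the first row's fraction.
    """
    if n_genotypes < 1:
        raise ValueError("need at least one genotype")
    sharing = variant_fragments(calls)
    counts = sharing.value_counts().reindex(range(1, n_genotypes + 1), fill_value=0)
    total = int(counts.sum())
    return pd.DataFrame(
        {
            "n_genotypes_sharing": counts.index,
            "n_variants": counts.to_numpy(),
            "fraction": counts.to_numpy() / total if total else np.zeros(len(counts)),
        }
    )


def singleton_fraction(calls: pd.DataFrame) -> float:
    sharing = variant_fragments(calls)
    return float((sharing == 1).mean()) if len(sharing) else 0.0


def window_proportions(
    calls: pd.DataFrame,
    positions: pd.DataFrame,
    window_bp: int = 1_500_000,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Proportion of variant fragments per physical window.

    Windows tile each chromosome; a window with no fragments gets a null
    (NaN) proportion. Returns (chromosome, win_start, win_end, n_fragments,
    n_variant, proportion).
    """
    var_ids = set(calls["fragment_id"].unique())
    pos = positions.copy()
    pos["is_variant"] = pos["fragment_id"].isin(var_ids)
    rows = []
    for chrom, sub in pos.groupby("chromosome", sort=True):
        length = (
            chrom_lengths[chrom]
            if chrom_lengths
            else int(sub["phys_start"].max()) + 1
        )
        edges = np.arange(0, length + window_bp, window_bp)
        idx = np.minimum(
            np.searchsorted(edges, sub["phys_start"].to_numpy(), side="right") - 1,
            len(edges) - 2,
        )
        for w in range(len(edges) - 1):
            inwin = sub[idx == w]
            n = len(inwin)
            k = int(inwin["is_variant"].sum())
            rows.append(
                {
                    "chromosome": chrom,
                    "win_start": int(edges[w]),
                    "win_end": int(edges[w + 1]),
                    "n_fragments": n,
                    "n_variant": k,
                    "proportion": k / n if n else np.nan,
                }
            )
    return pd.DataFrame(rows)


def chromosome_rates(
    calls: pd.DataFrame,
    positions: pd.DataFrame,
    window_bp: int = 1_500_000,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-chromosome variant proportion and a one-vs-rest Welch t-test.

    The test's sampling unit is the window-level variant proportion (the
    source data do not define a sampling unit for their chromosome tests, so
    the window is used). Chromosomes with fewer than 2 populated windows get
    a NaN p-value.
    """
    var_ids = set(calls["fragment_id"].unique())
    wins = window_proportions(calls, positions, window_bp, chrom_lengths)
    wins = wins.dropna(subset=["proportion"])
    rows = []
    for chrom, sub in positions.groupby("chromosome", sort=True):
        n = len(sub)
        k = int(sub["fragment_id"].isin(var_ids).sum())
        own = wins.loc[wins["chromosome"] == chrom, "proportion"].to_numpy()
        rest = wins.loc[wins["chromosome"] != chrom, "proportion"].to_numpy()
        if len(own) >= 2 and len(rest) >= 2:
            p = float(stats.ttest_ind(own, rest, equal_var=False).pvalue)
        else:
            warnings.warn(f"chromosome {chrom}: too few windows for a t-test", stacklevel=2)
            p = np.nan
        rows.append(
            {
                "chromosome": chrom,
                "n_fragments": n,
                "n_variant": k,
                "proportion": k / n if n else 0.0,
                "t_test_p": p,
            }
        )
    return pd.DataFrame(rows)


def group_difference_profile(
    calls: pd.DataFrame,
    positions: pd.DataFrame,
    groups: dict[str, str],
    window_bp: int = 1_500_000,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-window difference between wild and cultivated variant counts.

    A fragment counts for a group when it is called in at least one genotype
    of that group. Returns window rows with n_wild, n_cultivated and
    difference (wild - cultivated), plus summary attributes in
    ``DataFrame.attrs`` (n_positive / n_negative windows).
    """
    glabels = set(groups.values())
    if not {"wild", "cultivated"} <= glabels:
        raise ValueError("groups must label both 'wild' and 'cultivated' genotypes")
    ann = calls.copy()
    ann["group"] = ann["genotype"].map(groups)
    if ann["group"].isna().any():
        raise ValueError("calls contain genotypes without a group label")
    wild_ids = set(ann.loc[ann["group"] == "wild", "fragment_id"])
    cult_ids = set(ann.loc[ann["group"] == "cultivated", "fragment_id"])
    pos = positions.copy()
    pos["w"] = pos["fragment_id"].isin(wild_ids)
    pos["c"] = pos["fragment_id"].isin(cult_ids)
    rows = []
    for chrom, sub in pos.groupby("chromosome", sort=True):
        length = (
            chrom_lengths[chrom] if chrom_lengths else int(sub["phys_start"].max()) + 1
        )
        edges = np.arange(0, length + window_bp, window_bp)
        idx = np.minimum(
            np.searchsorted(edges, sub["phys_start"].to_numpy(), side="right") - 1,
            len(edges) - 2,
        )
        for w in range(len(edges) - 1):
            inwin = sub[idx == w]
            nw, nc = int(inwin["w"].sum()), int(inwin["c"].sum())
            rows.append(
                {
                    "chromosome": chrom,
                    "win_start": int(edges[w]),
                    "win_end": int(edges[w + 1]),
                    "n_wild": nw,
                    "n_cultivated": nc,
                    "difference": nw - nc,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["n_positive"] = int((out["difference"] > 0).sum())
    out.attrs["n_negative"] = int((out["difference"] < 0).sum())
    return out


def recombination_cnv_correlation(
    calls: pd.DataFrame,
    positions: pd.DataFrame,
    genetic_map: pd.DataFrame,
    bin_bp: int = 10_000_000,
) -> tuple[float, float, pd.DataFrame]:
    """Spearman correlation between recombination rate and CNV frequency.

    All chromosomes are pooled; per ``bin_bp`` bin the recombination rate is
    cM/Mb from map positions linearly interpolated at the bin edges, and the
    CNV frequency is the proportion of the bin's fragments that are variant.
    Returns (rho, p-value, per-bin table); raises for fewer than 3 populated
    bins.
    """
    var_ids = set(calls["fragment_id"].unique())
    rows = []
    for chrom, sub in positions.groupby("chromosome", sort=True):
        gmap = genetic_map[genetic_map["chromosome"] == chrom].sort_values("bp")
        if len(gmap) < 2:
            continue
        bp = gmap["bp"].to_numpy(float)
        cm = gmap["cM"].to_numpy(float)
        length = max(int(bp[-1]), int(sub["phys_start"].max()) + 1)
        edges = np.arange(0, length + bin_bp, bin_bp)
        idx = np.minimum(
            np.searchsorted(edges, sub["phys_start"].to_numpy(), side="right") - 1,
            len(edges) - 2,
        )
        cm_at_edges = np.interp(edges, bp, cm)
        for w in range(len(edges) - 1):
            inbin = sub[idx == w]
            if not len(inbin):
                continue
            n = len(inbin)
            k = int(inbin["fragment_id"].isin(var_ids).sum())
            span_mb = (edges[w + 1] - edges[w]) / 1e6
            rows.append(
                {
                    "chromosome": chrom,
                    "bin_start": int(edges[w]),
                    "bin_end": int(edges[w + 1]),
                    "cm_per_mb": (cm_at_edges[w + 1] - cm_at_edges[w]) / span_mb,
                    "n_fragments": n,
                    "proportion": k / n,
                }
            )
    table = pd.DataFrame(rows)
    if len(table) < 3:
        raise ValueError("fewer than 3 populated bins: correlation undefined")
    rho, p = stats.spearmanr(table["cm_per_mb"], table["proportion"])
    return float(rho), float(p), table


def exon_overlap_summary(
    calls: pd.DataFrame,
    fragments: pd.DataFrame,
    annotation: pd.DataFrame,
) -> dict[str, float]:
    """Proportion of Up and Down calls on exon-overlapping fragments.

    ``annotation``: intervals (contig, start, end) in contig coordinates;
    overlap is >= 1 bp intersection, half-open. Returns
    {"UpCNV": ..., "DownCNV/PAV": ...}; empty annotation yields zeros with a
    warning.
    """
    from .calling import DOWN, UP

    if annotation.empty:
        warnings.warn("empty annotation: exon overlap proportions are 0", stacklevel=2)
        return {UP: 0.0, DOWN: 0.0}
    trees: dict[str, IntervalTree] = {}
    for row in annotation.itertuples(index=False):
        if row.end > row.start:
            trees.setdefault(row.contig, IntervalTree()).addi(row.start, row.end)
    frag = fragments.set_index("fragment_id")
    overlaps = {}
    for fid, row in frag.iterrows():
        tree = trees.get(row["contig"])
        overlaps[fid] = bool(tree.overlap(row["start"], row["end"])) if tree else False
    out = {}
    for klass in (UP, DOWN):
        sub = calls[calls["class"] == klass]
        if len(sub):
            out[klass] = float(np.mean([overlaps[f] for f in sub["fragment_id"]]))
        else:
            out[klass] = 0.0
    return out
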