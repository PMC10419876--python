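"""Methylome-transcriptome integration.

Joins the DMR-associated genes (DMGs) with the differentially expressed
genes (DEGs): set overlap, hyper/hypo x up/down classification, context
and feature distributions of the DMR links, methylation-transcription
correlation (Pearson R^2 and Spearman rho, overall and stratified), and a
per-gene report with one row per (gene, DMR link).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

RECORD_COLUMNS = [
    "gene_id", "dmr_id", "chrom", "start", "end",
    "context", "direction", "delta", "feature", "features",
    "log2fc", "de_status",
]


def overlap_dmg_deg(links: pd.DataFrame, degs: pd.DataFrame) -> pd.DataFrame:
    """Integration records: genes that are both a DMG and a DEG.

    ``links`` is the per-(gene, DMR) table from ``dmr.associate_dmrs``;
    ``degs`` the table from ``expression.call_degs``.  Genes with
    ``de_status == "none"`` are not DEGs.  Returns one row per (gene, DMR
    link) for genes in the intersection.
    """
    if degs["gene_id"].duplicated().any():
        dup = degs.loc[degs["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene id in DEG table: {dup!r}")
    deg_only = degs[degs["de_status"] != "none"]
    merged = links.merge(deg_only[["gene_id", "log2fc", "de_status"]], on="gene_id", how="inner")
    return merged[RECORD_COLUMNS].reset_index(drop=True)


def classify_quadrants(records: pd.DataFrame) -> pd.DataFrame:
    """2x2 tally of DMG-DEG genes: direction (hyper/hypo) x DE (up/down).

    Each (gene, direction) pair contributes once per direction the gene
    carries, so a gene with both hyper and hypo DMRs is counted in two
    cells and the tally total can exceed the gene count.
    """
    tally = pd.DataFrame(
        0, index=pd.Index(["hyper", "hypo"], name="direction"),
        columns=pd.Index(["up", "down"], name="de_status"),
    )
    if records.empty:
        return tally
    pairs = records[["gene_id", "direction", "de_status"]].drop_duplicates(
        subset=["gene_id", "direction"]
    )
    for row in pairs.itertuples(index=False):
        tally.loc[row.direction, row.de_status] += 1
    return tally


def distribution_by(records: pd.DataFrame, axis: str) -> pd.DataFrame:
    """Distribution of DMR links along ``axis`` ("context" or "feature").

    Proportions are computed over DMR *links*, not genes; for the feature
    axis every overlapped feature kind of a link is counted.
    """
    if records.empty:
        raise ValueError("empty record set")
    if axis == "context":
        values = records["context"]
    elif axis == "feature":
        values = records["features"].str.split(";").explode()
    else:
        raise ValueError(f"axis must be 'context' or 'feature', got {axis!r}")
    counts = values.value_counts()
    out = counts.rename_axis(axis).reset_index(name="count")
    out["proportion"] = out["count"] / out["count"].sum()
    return out


def scatter_pairs(
    links: pd.DataFrame,
    degs: pd.DataFrame,
    gene_set: str = "records",
) -> pd.DataFrame:
    """(delta ML, log2FC) pairs for the methylation-transcription scatter.

    Each gene contributes one point: its largest-|delta| DMR link versus
    its expression log2FC.  ``gene_set`` selects the genes plotted:

    * ``"records"`` - genes that are both DMG and DEG (the strict overlap),
    * ``"deg"``     - every DEG carrying at least one DMR link,
    * ``"linked"``  - every gene carrying a DMR link, DEG or not.
    """
    if gene_set not in ("records", "deg", "linked"):
        raise ValueError(f"unknown gene_set {gene_set!r}")
    if degs["gene_id"].duplicated().any():
        raise ValueError("duplicate gene id in DEG table")
    expr = degs.set_index("gene_id")
    if gene_set in ("records", "deg"):
        keep = set(expr.index[expr["de_status"] != "none"])
    else:
        keep = set(expr.index)
    sub = links[links["gene_id"].isin(keep)]
    if sub.empty:
        return pd.DataFrame(columns=["gene_id", "delta", "log2fc", "feature", "context"])
    best = (
        sub.assign(absd=sub["delta"].abs())
        .sort_values("absd", kind="mergesort")
        .groupby("gene_id")
        .tail(1)
        .copy()
    )
    best["log2fc"] = expr["log2fc"].reindex(best["gene_id"]).to_numpy()
    return best[["gene_id", "delta", "log2fc", "feature", "context"]].sort_values(
        "gene_id", kind="mergesort"
    ).reset_index(drop=True)


def _safe_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(Pearson R^2, Spearman rho); NaN when either vector is constant."""
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan, np.nan
    r = stats.pearsonr(x, y)[0]
    rho = stats.spearmanr(x, y)[0]  # average ranks on ties
    return float(r * r), float(rho)


def correlate(
    pairs: pd.DataFrame,
    strata: Sequence[str] = ("overall", "feature", "context", "feature_context"),
    min_n: int = 3,
) -> pd.DataFrame:
    """Pearson R^2 and Spearman rho of (delta, log2FC), per stratum.

    Strata with fewer than ``min_n`` pairs are not reported.  Stratum names
    are ``overall``, ``feature:<kind>``, ``context:<ctx>`` and
    ``<kind>|<ctx>``.
    """
    rows = []

    def add(name: str, sub: pd.DataFrame) -> None:
        if len(sub) < min_n:
            return
        r2, rho = _safe_corr(sub["delta"].to_numpy(float), sub["log2fc"].to_numpy(float))
        rows.append({"stratum": name, "n": len(sub), "r2": r2, "spearman_rho": rho})

    if "overall" in strata:
        add("overall", pairs)
    if "feature" in strata:
        for kind, sub in pairs.groupby("feature"):
            add(f"feature:{kind}", sub)
    if "context" in strata:
        for ctx, sub in pairs.groupby("context"):
            add(f"context:{ctx}", sub)
    if "feature_context" in strata:
        for (kind, ctx), sub in pairs.groupby(["feature", "context"]):
            add(f"{kind}|{ctx}", sub)
    return pd.DataFrame(rows, columns=["stratum", "n", "r2", "spearman_rho"])


def gene_report(
    records: pd.DataFrame,
    genes: Sequence[str],
    log2fc_by_timepoint: Mapping[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Per-gene report: one row per (gene, DMR link), 1-based coordinates.

    ``log2fc_by_timepoint`` optionally maps a timepoint label to a DEG
    table; each contributes a ``log2fc_<label>`` column.  Without it the
    record's own log2FC is reported.
    """
    known = set(records["gene_id"])
    unknown = [g for g in genes if g not in known]
    if unknown:
        raise ValueError(f"no integration record for gene(s) {unknown}")
    sub = records[records["gene_id"].isin(set(genes))].copy()
    out = pd.DataFrame({"gene_id": sub["gene_id"]})
    if log2fc_by_timepoint:
        for label, table in log2fc_by_timepoint.items():
            lfc = table.set_index("gene_id")["log2fc"]
            out[f"log2fc_{label}"] = lfc.reindex(sub["gene_id"]).to_numpy()
    else:
        out["log2fc"] = sub["log2fc"].to_numpy()
    out["delta_ml"] = sub["delta"].to_numpy()
    out["context"] = sub["context"].to_numpy()
    out["region"] = sub["feature"].to_numpy()
    out["start"] = sub["start"].to_numpy() + 1  # 1-based inclusive, report convention
    out["end"] = sub["end"].to_numpy()
    return out.sort_values(["gene_id", "start"], kind="mergesort").reset_index(drop=True)
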