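"""Methylation calling against the bisulfite non-conversion rate.

A cytosine that is truly unmethylated can still be read as methylated when
bisulfite conversion fails; the per-read probability of that event is the
non-conversion rate ``r``, estimated from a fully unmethylated control
contig (spiked-in or simulated).  A site with ``m`` methylated and ``u``
converted reads is called methylated when the one-sided upper-tail binomial
p-value P(X >= m), X ~ Binomial(m+u, r), survives Benjamini-Hochberg FDR
correction across all tested sites of the sample.

Methylation *level* over any region is the pooled read fraction
ML = mC / (mC + non-mC); a region with zero pooled coverage is undefined
(NaN), which is distinct from an ML of 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .contexts import revcomp

CONTEXTS = ("CG", "CHG", "CHH")


@dataclass(frozen=True)
class ConversionModel:
    """Non-conversion rate ``r`` and where it came from."""

    r: float
    source: str = "config"

    def __post_init__(self) -> None:
        if not 0.0 <= self.r < 0.5:
            raise ValueError(f"non-conversion rate must be in [0, 0.5), got {self.r}")


def estimate_r(counts: pd.DataFrame, control_chrom: str = "control") -> ConversionModel:
    """Estimate ``r`` as the pooled methylated-read fraction on the control contig."""
    sub = counts[counts["chrom"] == control_chrom]
    total = int(sub["m"].sum() + sub["u"].sum())
    if total == 0:
        raise ValueError(
            f"zero total coverage on control contig {control_chrom!r}; cannot estimate r"
        )
    return ConversionModel(float(sub["m"].sum()) / total, source="estimated-from-control-contig")


def call_sites(
    counts: pd.DataFrame,
    model: ConversionModel,
    alpha: float = 0.05,
    min_coverage: int = 4,
) -> pd.DataFrame:
    """Binomial methylation calls per site per sample.

    Sites with coverage below ``min_coverage`` are excluded from the test
    (and from the BH family).  BH adjustment is applied within each sample.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if (counts["m"] < 0).any() or (counts["u"] < 0).any():
        raise ValueError("negative read counts")
    cov = counts["m"] + counts["u"]
    out = counts.loc[cov >= min_coverage].copy()
    if out.empty:
        out["p"] = np.nan
        out["q"] = np.nan
        out["is_methylated"] = pd.Series(dtype=bool)
        return out
    n = (out["m"] + out["u"]).to_numpy()
    out["p"] = stats.binom.sf(out["m"].to_numpy() - 1, n, model.r)
    out["q"] = out.groupby("sample", sort=False)["p"].transform(
        lambda p: multipletests(p.to_numpy(), method="fdr_bh")[1]
    )
    out["is_methylated"] = out["q"] < alpha
    return out


def bin_genome(chrom_lengths: Mapping[str, int], width: int = 10_000) -> pd.DataFrame:
    """Tile each chromosome with non-overlapping bins; final partial bin kept."""
    if width <= 0:
        raise ValueError(f"bin width must be positive, got {width}")
    rows = []
    for chrom, length in chrom_lengths.items():
        for start in range(0, max(int(length), 1), width):
            end = min(start + width, int(length))
            rows.append(
                {
                    "region_id": f"{chrom}:{start}-{end}",
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                }
            )
    return pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end"])


def methylation_level(
    counts: pd.DataFrame,
    regions: pd.DataFrame,
    contexts: Sequence[str] | None = CONTEXTS,
) -> pd.DataFrame:
    """Pooled methylation level per region x context x sample.

    ``regions`` needs columns ``region_id, chrom, start, end`` (0-based
    half-open).  With ``contexts=None`` the three contexts are pooled into a
    single ``all`` row per region and sample.  The full grid is emitted:
    combinations with no covered site get m = u = 0 and ML = NaN.
    """
    if (regions["end"] <= regions["start"]).any():
        raise ValueError("degenerate region with end <= start")
    samples = sorted(counts["sample"].unique())
    ctx_levels = list(contexts) if contexts is not None else ["all"]
    by_chrom = {
        chrom: sub.sort_values("pos", kind="mergesort").reset_index(drop=True)
        for chrom, sub in counts.groupby("chrom", sort=False)
    }
    rows = []
    for region in regions.itertuples(index=False):
        sub = by_chrom.get(region.chrom)
        if sub is not None:
            pos = sub["pos"].to_numpy()
            lo = int(np.searchsorted(pos, region.start, side="left"))
            hi = int(np.searchsorted(pos, region.end, side="left"))
            inside = sub.iloc[lo:hi]
        else:
            inside = None
        if contexts is None:
            grouped = (
                inside.groupby("sample")[["m", "u"]].sum()
                if inside is not None and not inside.empty
                else pd.DataFrame(columns=["m", "u"])
            )
            pooled = {("all", s): grouped.loc[s] if s in grouped.index else None for s in samples}
        else:
            grouped = (
                inside.groupby(["context", "sample"])[["m", "u"]].sum()
                if inside is not None and not inside.empty
                else pd.DataFrame(columns=["m", "u"])
            )
            pooled = {
                (c, s): grouped.loc[(c, s)] if (c, s) in grouped.index else None
                for c in ctx_levels
                for s in samples
            }
        for (ctx, sample), vals in pooled.items():
            m = int(vals["m"]) if vals is not None else 0
            u = int(vals["u"]) if vals is not None else 0
            rows.append(
                {
                    "region_id": region.region_id,
                    "chrom": region.chrom,
                    "start": region.start,
                    "end": region.end,
                    "context": ctx,
                    "sample": sample,
                    "m": m,
                    "u": u,
                    "ml": m / (m + u) if m + u > 0 else np.nan,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["region_id", "chrom", "start", "end", "context", "sample", "m", "u", "ml"],
    )


def bulk_ml(counts: pd.DataFrame, by_context: bool = True) -> pd.DataFrame:
    """Genome-wide pooled ML per sample (optionally per context)."""
    keys = ["sample", "context"] if by_context else ["sample"]
    g = counts.groupby(keys)[["m", "u"]].sum().reset_index()
    cov = g["m"] + g["u"]
    g["ml"] = np.where(cov > 0, g["m"] / cov.replace(0, np.nan), np.nan)
    return g


def amplicon_ml(
    reference: str,
    reads: Iterable[str],
    strand: str = "+",
) -> pd.DataFrame:
    """Targeted-bisulfite methylation level over a gap-free amplicon.

    At each reference cytosine on the stated strand a read base C counts as
    methylated and T as converted; anything else is ignored.  Returns pooled
    counts and ML per context plus an ``all`` row covering every reference C
    (including those whose context cannot be determined near the amplicon
    edge).
    """
    if strand not in "+-":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    reads = [r.upper() for r in reads]
    reference = reference.upper()
    for i, read in enumerate(reads):
        if len(read) != len(reference):
            raise ValueError(
                f"read {i} length {len(read)} != reference length {len(reference)}"
            )
    if strand == "-":
        reference = revcomp(reference)
        reads = [revcomp(r) for r in reads]
    tallies = {ctx: [0, 0] for ctx in (*CONTEXTS, "all")}
    for i, base in enumerate(reference):
        if base != "C":
            continue
        ctx = None
        if i + 2 < len(reference):
            b1, b2 = reference[i + 1], reference[i + 2]
            if b1 != "N" and b2 != "N":
                ctx = "CG" if b1 == "G" else ("CHG" if b2 == "G" else "CHH")
        for read in reads:
            b = read[i]
            if b == "C":
                tallies["all"][0] += 1
                if ctx:
                    tallies[ctx][0] += 1
            elif b == "T":
                tallies["all"][1] += 1
                if ctx:
                    tallies[ctx][1] += 1
    rows = []
    for ctx, (m, u) in tallies.items():
        rows.append(
            {"context": ctx, "m": m, "u": u, "ml": m / (m + u) if m + u > 0 else np.nan}
        )
    return pd.DataFrame(rows, columns=["context", "m", "u", "ml"])
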