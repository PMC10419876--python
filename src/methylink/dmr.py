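"""Differentially methylated regions (DMRs) and their associated genes (DMGs).

The caller slides fixed windows per cytosine context, pools replicate read
counts per condition within the window, and tests the 2x2 table
(m_case, u_case; m_control, u_control) with a two-sided Fisher's exact
test.  P-values are BH-adjusted across the windows of a context; windows
passing q < alpha and |delta ML| >= delta_min are merged when they share a
direction and lie within ``merge_gap`` of each other, and merged-region
statistics are recomputed on the pooled counts.

The sign convention is case minus control (iron-deficient minus
iron-sufficient in the default study design), so delta > 0 is *hyper*
(induced methylation) and delta < 0 is *hypo*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .methylcall import CONTEXTS

logger = logging.getLogger(__name__)

GENE_FEATURE_KINDS = ("promoter", "five_prime_UTR", "exon", "intron", "three_prime_UTR")
# precedence when a single representative feature is needed for a DMR link
FEATURE_PRECEDENCE = ("promoter", "exon", "intron", "five_prime_UTR", "three_prime_UTR")

DMR_COLUMNS = [
    "dmr_id", "chrom", "start", "end", "context",
    "ml_case", "ml_control", "delta", "p", "q", "direction",
]


@dataclass(frozen=True)
class DmrParams:
    """Sliding-window DMR parameters (bp sizes, ML delta, FDR level)."""

    window: int = 200
    step: int = 50
    delta_min: float = 0.1
    alpha: float = 0.05
    merge_gap: int = 100

    def __post_init__(self) -> None:
        if self.window <= 0 or self.step <= 0:
            raise ValueError("window and step must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.delta_min <= 1:
            raise ValueError("delta_min must be in (0, 1]")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")


def fisher_twosided(mc: int, uc: int, mk: int, uk: int) -> float:
    """Two-sided Fisher's exact p-value for the 2x2 table [[mc, uc], [mk, uk]].

    Sums the hypergeometric probabilities of all tables at least as extreme
    (probability mass <= the observed one, with a small relative tolerance
    for float ties) conditional on the margins.  Equivalent to
    ``scipy.stats.fisher_exact(..., alternative="two-sided")`` but much
    faster for the caller's many-windows workload.
    """
    N = mc + uc + mk + uk
    K = mc + mk          # total methylated reads
    n1 = mc + uc         # case margin
    if N == 0 or K == 0 or K == N or n1 == 0 or n1 == N:
        return 1.0
    lo = max(0, K - (N - n1))
    hi = min(K, n1)
    k = np.arange(lo, hi + 1)
    # hypergeometric log-pmf over the full support, via log-gamma
    logpmf = (
        gammaln(K + 1) - gammaln(k + 1) - gammaln(K - k + 1)
        + gammaln(N - K + 1) - gammaln(n1 - k + 1) - gammaln(N - K - n1 + k + 1)
        - (gammaln(N + 1) - gammaln(n1 + 1) - gammaln(N - n1 + 1))
    )
    observed = logpmf[mc - lo]
    extreme = logpmf[logpmf <= observed + np.log1p(1e-7)]
    return float(min(1.0, np.exp(extreme).sum()))


def classify_direction(delta: float) -> str:
    """hyper if delta > 0, hypo if delta < 0; delta == 0 is not a DMR."""
    if delta > 0:
        return "hyper"
    if delta < 0:
        return "hypo"
    raise ValueError("delta = 0 has no direction (excluded upstream by delta_min)")


def _pooled_positions(sub: pd.DataFrame, samples: Sequence[str]) -> pd.DataFrame:
    s = sub[sub["sample"].isin(samples)]
    return s.groupby("pos")[["m", "u"]].sum()


def call_dmrs(
    counts: pd.DataFrame,
    case_samples: Sequence[str],
    control_samples: Sequence[str],
    chrom_lengths: Mapping[str, int],
    params: DmrParams | None = None,
    contexts: Sequence[str] = CONTEXTS,
) -> pd.DataFrame:
    """Call DMRs (case vs control) per context over ``chrom_lengths``.

    ``counts`` is a tidy per-site table with columns
    ``chrom, pos, strand, context, sample, m, u``; replicates are pooled by
    summation within each condition.
    """
    params = params or DmrParams()
    case_samples = list(case_samples)
    control_samples = list(control_samples)
    if not case_samples or not control_samples:
        raise ValueError("each condition needs at least one sample")
    for label, samp in (("case", case_samples), ("control", control_samples)):
        if len(samp) < 2:
            logger.warning(
                "condition %r has no replication (%d sample); pooled test still runs",
                label, len(samp),
            )
    pooled_cache: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    any_window = False
    merged_all = []
    for context in contexts:
        window_rows = []
        for chrom, length in chrom_lengths.items():
            sub = counts[(counts["context"] == context) & (counts["chrom"] == chrom)]
            if sub.empty:
                continue
            pc = _pooled_positions(sub, case_samples)
            pk = _pooled_positions(sub, control_samples)
            pos = np.union1d(pc.index.to_numpy(), pk.index.to_numpy())
            case = pc.reindex(pos, fill_value=0)
            ctrl = pk.reindex(pos, fill_value=0)
            cum = {
                "mc": np.concatenate([[0], np.cumsum(case["m"].to_numpy())]),
                "uc": np.concatenate([[0], np.cumsum(case["u"].to_numpy())]),
                "mk": np.concatenate([[0], np.cumsum(ctrl["m"].to_numpy())]),
                "uk": np.concatenate([[0], np.cumsum(ctrl["u"].to_numpy())]),
            }
            pooled_cache[(context, chrom)] = (pos, cum)
            for start in range(0, int(length), params.step):
                end = min(start + params.window, int(length))
                if end <= start:
                    continue
                lo = int(np.searchsorted(pos, start, side="left"))
                hi = int(np.searchsorted(pos, end, side="left"))
                mc = int(cum["mc"][hi] - cum["mc"][lo])
                uc = int(cum["uc"][hi] - cum["uc"][lo])
                mk = int(cum["mk"][hi] - cum["mk"][lo])
                uk = int(cum["uk"][hi] - cum["uk"][lo])
                if mc + uc == 0 or mk + uk == 0:
                    continue
                any_window = True
                delta = mc / (mc + uc) - mk / (mk + uk)
                p = fisher_twosided(mc, uc, mk, uk)
                window_rows.append(
                    {"chrom": chrom, "start": start, "end": end, "delta": delta, "p": p}
                )
        if not window_rows:
            continue
        windows = pd.DataFrame(window_rows)
        windows["q"] = multipletests(windows["p"].to_numpy(), method="fdr_bh")[1]
        sig = windows[(windows["q"] < params.alpha) & (windows["delta"].abs() >= params.delta_min)]
        if sig.empty:
            continue
        merged = _merge_windows(sig, params)
        for region in merged:
            chrom, start, end, _direction = region
            pos, cum = pooled_cache[(context, chrom)]
            lo = int(np.searchsorted(pos, start, side="left"))
            hi = int(np.searchsorted(pos, end, side="left"))
            mc = int(cum["mc"][hi] - cum["mc"][lo])
            uc = int(cum["uc"][hi] - cum["uc"][lo])
            mk = int(cum["mk"][hi] - cum["mk"][lo])
            uk = int(cum["uk"][hi] - cum["uk"][lo])
            ml_case = mc / (mc + uc)
            ml_control = mk / (mk + uk)
            delta = ml_case - ml_control
            p = fisher_twosided(mc, uc, mk, uk)
            merged_all.append(
                {
                    "chrom": chrom, "start": start, "end": end, "context": context,
                    "ml_case": ml_case, "ml_control": ml_control,
                    "delta": delta, "p": p,
                }
            )
    if not any_window:
        raise ValueError("no covered windows in either condition")
    if not merged_all:
        return pd.DataFrame(columns=DMR_COLUMNS)
    out = pd.DataFrame(merged_all)
    # recomputed statistics must still honour the DMR contract
    out["q"] = np.nan
    for context in out["context"].unique():
        mask = out["context"] == context
        out.loc[mask, "q"] = multipletests(out.loc[mask, "p"].to_numpy(), method="fdr_bh")[1]
    out = out[(out["q"] < params.alpha) & (out["delta"].abs() >= params.delta_min)].copy()
    if out.empty:
        return pd.DataFrame(columns=DMR_COLUMNS)
    out["direction"] = np.where(out["delta"] > 0, "hyper", "hypo")
    out["dmr_id"] = [
        f"{r.chrom}:{r.start}-{r.end}:{r.context}" for r in out.itertuples(index=False)
    ]
    out = out.sort_values(["chrom", "start", "context"], kind="mergesort").reset_index(drop=True)
    return out[DMR_COLUMNS]


def _merge_windows(sig: pd.DataFrame, params: DmrParams) -> list[tuple[str, int, int, str]]:
    """Merge significant windows of equal direction within merge_gap."""
    regions: list[tuple[str, int, int, str]] = []
    sig = sig.sort_values(["chrom", "start"], kind="mergesort")
    cur = None
    for w in sig.itertuples(index=False):
        direction = "hyper" if w.delta > 0 else "hypo"
        if (
            cur is not None
            and w.chrom == cur[0]
            and direction == cur[3]
            and w.start - cur[2] <= params.merge_gap
        ):
            cur = (cur[0], cur[1], max(cur[2], w.end), cur[3])
        else:
            if cur is not None:
                regions.append(cur)
            cur = (w.chrom, int(w.start), int(w.end), direction)
    if cur is not None:
        regions.append(cur)
    return regions


def promoter_interval(
    gene_start: int, gene_end: int, strand: str, promoter_length: int, chrom_length: int
) -> tuple[int, int]:
    """Strand-aware promoter upstream of the TSS, truncated at contig edges."""
    if strand == "+":
        return max(0, gene_start - promoter_length), gene_start
    return gene_end, min(int(chrom_length), gene_end + promoter_length)


def build_features(
    genes: pd.DataFrame,
    subfeatures: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    promoter_length: int = 2000,
    repeats: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Full feature table: promoter, UTRs, exons, derived introns, repeats.

    ``genes`` has ``gene_id, chrom, start, end, strand``; ``subfeatures``
    has ``gene_id, chrom, kind, start, end, strand`` for UTRs and exons.
    Introns are derived as the gene body minus the annotated subfeatures.
    """
    rows = []
    for g in genes.itertuples(index=False):
        ps, pe = promoter_interval(
            int(g.start), int(g.end), g.strand, promoter_length, chrom_lengths[g.chrom]
        )
        if pe > ps:
            rows.append(
                {"gene_id": g.gene_id, "chrom": g.chrom, "kind": "promoter",
                 "start": ps, "end": pe, "strand": g.strand}
            )
        sub = subfeatures[subfeatures["gene_id"] == g.gene_id].sort_values("start")
        for f in sub.itertuples(index=False):
            rows.append(
                {"gene_id": g.gene_id, "chrom": g.chrom, "kind": f.kind,
                 "start": int(f.start), "end": int(f.end), "strand": g.strand}
            )
        # introns: gaps of the gene body not covered by any subfeature
        covered = sorted((int(f.start), int(f.end)) for f in sub.itertuples(index=False))
        cursor = int(g.start)
        for s, e in covered:
            if s > cursor:
                rows.append(
                    {"gene_id": g.gene_id, "chrom": g.chrom, "kind": "intron",
                     "start": cursor, "end": s, "strand": g.strand}
                )
            cursor = max(cursor, e)
        if cursor < int(g.end):
            rows.append(
                {"gene_id": g.gene_id, "chrom": g.chrom, "kind": "intron",
                 "start": cursor, "end": int(g.end), "strand": g.strand}
            )
    if repeats is not None:
        for r in repeats.itertuples(index=False):
            rows.append(
                {"gene_id": pd.NA, "chrom": r.chrom, "kind": "repeat",
                 "start": int(r.start), "end": int(r.end), "strand": "."}
            )
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "kind", "start", "end", "strand"])


def associate_dmrs(dmrs: pd.DataFrame, features: pd.DataFrame) -> pd.DataFrame:
    """Link DMRs to genes through >=1 bp overlap with promoter or gene body.

    Returns one row per (gene, DMR) link with every overlapped feature kind
    recorded (``features`` column, semicolon-joined in precedence order) and
    a single representative ``feature`` by precedence.
    """
    gene_feats = features[
        features["kind"].isin(GENE_FEATURE_KINDS) & features["gene_id"].notna()
    ]
    rows = []
    for d in dmrs.itertuples(index=False):
        hits = gene_feats[
            (gene_feats["chrom"] == d.chrom)
            & (gene_feats["start"] < d.end)
            & (gene_feats["end"] > d.start)
        ]
        if hits.empty:
            continue
        for gene_id, kinds in hits.groupby("gene_id")["kind"]:
            ordered = [k for k in FEATURE_PRECEDENCE if k in set(kinds)]
            rows.append(
                {
                    "gene_id": gene_id,
                    "dmr_id": d.dmr_id,
                    "chrom": d.chrom,
                    "start": d.start,
                    "end": d.end,
                    "context": d.context,
                    "direction": d.direction,
                    "delta": d.delta,
                    "feature": ordered[0],
                    "features": ";".join(ordered),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "dmr_id", "chrom", "start", "end",
            "context", "direction", "delta", "feature", "features",
        ],
    )


def aggregate_dmgs(links: pd.DataFrame) -> pd.DataFrame:
    """One row per DMR-associated gene, aggregating its DMR links."""
    if links.empty:
        return pd.DataFrame(
            columns=["gene_id", "n_dmrs", "contexts", "directions", "features"]
        )
    rows = []
    for gene_id, sub in links.groupby("gene_id"):
        rows.append(
            {
                "gene_id": gene_id,
                "n_dmrs": sub["dmr_id"].nunique(),
                "contexts": ";".join(sorted(sub["context"].unique())),
                "directions": ";".join(sorted(sub["direction"].unique())),
                "features": ";".join(
                    k for k in FEATURE_PRECEDENCE
                    if k in {f for fs in sub["features"] for f in fs.split(";")}
                ),
            }
        )
    return pd.DataFrame(rows)
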