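"""RPKM quantification and differential expression calling.

Expression is summarised as RPKM (reads per kilobase of transcript per
million mapped reads).  Differential expression between two conditions is
assessed with an unequal-variance (Welch) two-sample t-test on
log2(RPKM + pseudocount) followed by Benjamini-Hochberg adjustment across
genes; a gene is a DEG when |log2FC| >= fc_min and q < alpha, with the
fold change computed as the mean log2(RPKM + pseudocount) difference,
case minus control.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEG_COLUMNS = ["gene_id", "log2fc", "p", "q", "de_status"]


def rpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """RPKM matrix from a (gene x sample) count matrix.

    ``gene_lengths`` is in bp, indexed by gene; ``library_sizes`` defaults
    to the column sums of ``counts``.
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(counts.index[lengths.isna()])[:5]
        raise ValueError(f"missing gene length for {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = library_sizes.reindex(counts.columns)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts.div(lengths / 1e3, axis=0).div(library_sizes / 1e6, axis=1)


def call_degs(
    rpkm_matrix: pd.DataFrame,
    case_samples: Sequence[str],
    control_samples: Sequence[str],
    fc_min: float = 1.0,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Welch-t DEG calls on log2(RPKM + pseudocount), case vs control."""
    case_samples = list(case_samples)
    control_samples = list(control_samples)
    if len(case_samples) < 2 or len(control_samples) < 2:
        raise ValueError("need >=2 replicates per condition")
    log = np.log2(rpkm_matrix + pseudocount)
    a = log[case_samples].to_numpy()
    b = log[control_samples].to_numpy()
    lfc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    # zero variance in both groups: identical values -> p = 1; a deterministic
    # offset with no within-group noise is maximally significant
    p = np.where(np.isnan(p), np.where(lfc == 0.0, 1.0, 0.0), p)
    q = multipletests(p, method="fdr_bh")[1]
    de_status = np.where(
        (np.abs(lfc) >= fc_min) & (q < alpha),
        np.where(lfc > 0, "up", "down"),
        "none",
    )
    return pd.DataFrame(
        {
            "gene_id": rpkm_matrix.index,
            "log2fc": lfc,
            "p": p,
            "q": q,
            "de_status": de_status,
        }
    ).reset_index(drop=True)
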