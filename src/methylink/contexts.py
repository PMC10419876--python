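"""Enumerate cytosines with CG/CHG/CHH sequence context on both strands.

In plants the three cytosine contexts (H = A, C or T) are maintained by
distinct methylation pathways, so every downstream statistic here is kept
context-resolved.  A site's context is a deterministic function of the two
bases immediately downstream of the cytosine *on its own strand*:

* next base G                      -> CG
* next base H, base after that G   -> CHG
* both downstream bases H          -> CHH

Minus-strand sites appear as G on the plus strand; their context is read
from the reverse complement.  Sites whose two downstream bases are not
defined (contig edge, or an N inside the trinucleotide) are skipped rather
than emitted with an unknown context.  Coordinates are 0-based half-open
throughout the library; conversion to 1-based happens only in file I/O.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

SITE_COLUMNS = ["chrom", "pos", "strand", "context", "trinucleotide"]

_C, _G, _N = ord("C"), ord("G"), ord("N")

# byte-level complement table (only ACGTN occur after validation)
_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP[_a] = _b

_CTX_NAMES = np.array(["CG", "CHG", "CHH"])


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N sequence (case preserved)."""
    return seq.translate(COMPLEMENT)[::-1]


def _validate(chrom: str, arr: np.ndarray) -> None:
    ok = np.isin(arr, np.frombuffer(b"ACGTN", dtype=np.uint8))
    if not ok.all():
        bad = sorted({chr(b) for b in arr[~ok]})
        raise ValueError(
            f"non-nucleotide character(s) {bad} in sequence {chrom!r}; "
            "only A/C/G/T/N are accepted"
        )


def _context_codes(b1: np.ndarray, b2: np.ndarray) -> np.ndarray:
    # 0=CG, 1=CHG, 2=CHH; caller guarantees b1/b2 are A/C/G/T
    return np.where(b1 == _G, 0, np.where(b2 == _G, 1, 2))


def _sites_one_chrom(chrom: str, seq: str) -> pd.DataFrame:
    seq = seq.upper()
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    _validate(chrom, arr)
    frames = []
    if arr.size >= 3:
        # plus strand: C with two defined downstream bases to the right
        p = np.flatnonzero(arr[:-2] == _C)
        b1, b2 = arr[p + 1], arr[p + 2]
        keep = (b1 != _N) & (b2 != _N)
        p, b1, b2 = p[keep], b1[keep], b2[keep]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": p,
                    "strand": "+",
                    "context": _CTX_NAMES[_context_codes(b1, b2)],
                    "trinucleotide": [seq[i : i + 3] for i in p],
                }
            )
        )
        # minus strand: G on the plus strand, downstream = leftwards
        g = np.flatnonzero(arr[2:] == _G) + 2
        b1 = _COMP[arr[g - 1]]
        b2 = _COMP[arr[g - 2]]
        keep = (b1 != _N) & (b2 != _N)
        g, b1, b2 = g[keep], b1[keep], b2[keep]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": g,
                    "strand": "-",
                    "context": _CTX_NAMES[_context_codes(b1, b2)],
                    "trinucleotide": [revcomp(seq[i - 2 : i + 1]) for i in g],
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=SITE_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def extract_contexts(genome: Mapping[str, str]) -> pd.DataFrame:
    """Enumerate every context-resolvable cytosine of ``genome``.

    Parameters
    ----------
    genome
        Mapping of sequence name to A/C/G/T/N string.

    Returns
    -------
    DataFrame with columns ``chrom, pos, strand, context, trinucleotide``,
    sorted by (chrom, pos, strand); ``pos`` is the 0-based offset of the
    cytosine on the plus strand and ``trinucleotide`` is read 5'->3' on the
    site's own strand.
    """
    frames = [_sites_one_chrom(chrom, seq) for chrom, seq in genome.items()]
    frames = [f for f in frames if not f.empty]
    if not frames:
        return pd.DataFrame(columns=SITE_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["chrom", "pos", "strand"], kind="mergesort")
    return out.reset_index(drop=True)
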