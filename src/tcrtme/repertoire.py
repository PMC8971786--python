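"""TCR-beta repertoire diversity metrics.

A repertoire is a :class:`pandas.DataFrame` with one row per unique clonotype
(columns ``clonotype_id`` and integer ``count`` >= 1; ``junction_aa`` optional).
The metrics implemented here are the standard descriptors of clonal structure
used in bulk CDR3 immunosequencing studies:

``total_count``
    number of sequenced templates/reads (library-size proxy).
``unique_count``
    number of distinct clonotypes observed.
``clonal_proportion``
    unique / total — the fraction of reads that are "new" clones; rises when a
    repertoire becomes more evenly sampled.
``d50``
    the minimum number of distinct clonotypes whose summed reads reach at least
    half of all reads. Small D50 = a few expanded clones dominate.
``normalized_shannon``
    Shannon entropy of clonotype frequencies divided by its maximum ln(N)
    (Pielou evenness): 0 for a monoclonal repertoire, 1 for a perfectly even one.
``abundance_groups``
    fraction of reads held by decade rank bins of the most-expanded clonotypes
    (the stacked relative-abundance representation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import EmptyRepertoireError

__all__ = [
    "RepertoireSummary",
    "total_count",
    "unique_count",
    "clonal_proportion",
    "normalized_shannon",
    "d50",
    "abundance_groups",
    "summarize",
]

DEFAULT_BIN_EDGES: tuple[int, ...] = (10, 100, 1000, 10000)


@dataclass
class RepertoireSummary:
    """Per-sample bundle of all repertoire metrics.

    ``frequencies`` maps clonotype_id -> count/total and sums to 1 within 1e-12.
    """

    total_tcr: int
    unique_tcr: int
    clonal_proportion: float
    d50: int
    h_norm: float
    frequencies: dict[str, float] = field(repr=False)
    abundance_groups: dict[str, float] = field(default_factory=dict)


def _validate(rep: pd.DataFrame) -> pd.DataFrame:
    if rep is None or len(rep) == 0:
        raise EmptyRepertoireError("repertoire has no clonotypes")
    if "count" not in rep.columns or "clonotype_id" not in rep.columns:
        raise ValueError("repertoire needs 'clonotype_id' and 'count' columns")
    counts = rep["count"].to_numpy()
    if (counts < 1).any():
        raise ValueError("all clonotype counts must be >= 1")
    if rep["clonotype_id"].duplicated().any():
        raise ValueError("clonotype_id values must be unique within a repertoire")
    return rep


def total_count(rep: pd.DataFrame) -> int:
    """Total number of TCR reads/templates (sum of clonotype counts)."""
    _validate(rep)
    return int(rep["count"].sum())


def unique_count(rep: pd.DataFrame) -> int:
    """Number of distinct clonotypes."""
    _validate(rep)
    return int(len(rep))


def clonal_proportion(rep: pd.DataFrame) -> float:
    """Unique clonotypes per read: ``unique / total`` in (0, 1]."""
    _validate(rep)
    return len(rep) / float(rep["count"].sum())


def normalized_shannon(rep: pd.DataFrame, denominator: str = "unique") -> float:
    """Normalized Shannon entropy HNorm = -sum(p_i ln p_i) / ln(N).

    With ``denominator="unique"`` (default) N is the number of unique
    clonotypes, i.e. Pielou evenness, which attains 1 exactly for an even
    repertoire and 0 for a monoclonal one (the 0/0 case at N=1 is defined as 0:
    a single clone has no evenness). ``denominator="reads"`` instead divides by
    ln(total reads) as a sensitivity alternative; it never reaches 1 unless
    every read is a distinct clonotype.
    """
    _validate(rep)
    counts = rep["count"].to_numpy(dtype=float)
    total = counts.sum()
    p = counts / total
    h = float(-(p * np.log(p)).sum())
    if denominator == "unique":
        n = len(counts)
    elif denominator == "reads":
        n = total
    else:
        raise ValueError(f"denominator must be 'unique' or 'reads', got {denominator!r}")
    if n <= 1:
        return 0.0
    return h / math.log(n)


def _sorted_counts(rep: pd.DataFrame) -> np.ndarray:
    # descending count, ties broken by clonotype_id ascending for determinism
    ordered = rep.sort_values(
        ["count", "clonotype_id"], ascending=[False, True], kind="mergesort"
    )
    return ordered["count"].to_numpy()


def d50(rep: pd.DataFrame) -> int:
    """Minimum number of top clonotypes covering >= 50% of all reads."""
    _validate(rep)
    counts = _sorted_counts(rep)
    cum = np.cumsum(counts)
    total = cum[-1]
    # integer comparison avoids float boundary artefacts: 2*cum >= total <=> cum/total >= 0.5
    k = int(np.argmax(2 * cum >= total)) + 1
    return k


def abundance_groups(
    rep: pd.DataFrame, bin_edges: tuple[int, ...] = DEFAULT_BIN_EDGES
) -> dict[str, float]:
    """Fraction of reads held by clonotype rank bins.

    Clones are ranked descending by count (ties by id); with the default edges
    the bins are ranks 1-10, 11-100, 101-1000, 1001-10000 and 10001+. Fractions
    sum to 1 within 1e-12; empty bins report 0.
    """
    _validate(rep)
    edges = tuple(int(e) for e in bin_edges)
    if len(edges) == 0 or any(b <= a for a, b in zip((0,) + edges, edges)):
        raise ValueError("bin_edges must be strictly increasing positive integers")
    counts = _sorted_counts(rep)
    total = float(counts.sum())
    bounds = (0,) + edges
    out: dict[str, float] = {}
    for lo, hi in zip(bounds, edges):
        out[f"{lo + 1}-{hi}"] = float(counts[lo:hi].sum()) / total
    out[f"{edges[-1] + 1}+"] = float(counts[edges[-1]:].sum()) / total
    return out


def summarize(
    rep: pd.DataFrame,
    bin_edges: tuple[int, ...] = DEFAULT_BIN_EDGES,
    denominator: str = "unique",
) -> RepertoireSummary:
    """Compute every repertoire metric at once, consistently with the
    single-metric functions."""
    _validate(rep)
    total = total_count(rep)
    freqs = {
        str(cid): c / total for cid, c in zip(rep["clonotype_id"], rep["count"])
    }
    return RepertoireSummary(
        total_tcr=total,
        unique_tcr=unique_count(rep),
        clonal_proportion=clonal_proportion(rep),
        d50=d50(rep),
        h_norm=normalized_shannon(rep, denominator=denominator),
        frequencies=freqs,
        abundance_groups=abundance_groups(rep, bin_edges=bin_edges),
    )
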