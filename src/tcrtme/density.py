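"""Immune-cell density quantification from segmented-cell observations.

Two acquisition paths feed the same downstream statistics:

* **IHC / tissue microarray** — per-core counts of immunopositive and
  immunonegative cells plus the core's malignant-epithelial-cell fraction.
  Cores with less than 50% tumor cells are excluded; percentage
  immunoreactivity is ``100 * positive / (positive + negative)`` per core and
  the per-case value is the unweighted mean over that case's retained cores.

* **multiplex immunofluorescence** — per-cell phenotype calls with a
  tumor-nest / stroma compartment label. Density of a phenotype combination
  is the percentage of matching cells among all nucleated cells of the
  requested compartment (cells pooled over fields; a per-field-average
  alternative is exposed).

Densities here are percentages of nucleated cells (the quantity the scoring
protocol defines), not cells per area; figure-style values use the
``log2(density + 1)`` transform.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import PairingError, UndefinedStatisticError

__all__ = [
    "DensityRecord",
    "parse_phenotype",
    "filter_cores",
    "core_immunoreactivity",
    "case_density",
    "mif_density",
    "log2p1",
    "paired_delta",
    "density_table",
]

logger = logging.getLogger(__name__)

MIN_TUMOR_FRACTION = 0.5
KNOWN_MARKERS = {"CD3", "CD4", "CD8", "FOXP3", "PDL1", "GZMB", "CD20", "CD57", "CD68"}

_PHENOTYPE_RE = re.compile(r"([A-Za-z0-9]+)([+\-−])")


@dataclass
class DensityRecord:
    """One density measurement: sample x timepoint x phenotype x compartment."""

    sample_id: str
    timepoint: str  # "pre" | "post"
    marker: str  # phenotype-combination label, e.g. "FOXP3+CD3+"
    compartment: str  # "tumor" | "stroma" | "total"
    density: float  # percent of nucleated cells (or averaged core percentage)

    def __post_init__(self) -> None:
        if not (0 <= self.density <= 100):
            raise ValueError(f"density must be in [0, 100], got {self.density}")

    @property
    def density_log2(self) -> float:
        return log2p1(self.density)


def parse_phenotype(label: str) -> list[tuple[str, bool]]:
    """Parse a phenotype-combination label into (marker, required-positivity).

    ``"FOXP3+CD3+"`` -> both markers required positive; ``"CD8+FOXP3-"`` ->
    CD8 positive and FOXP3 negative. The combination is a conjunction: a cell
    matches only if every listed marker has the required state.
    """
    label = label.strip()
    tokens = _PHENOTYPE_RE.findall(label)
    if not tokens or "".join(m + s for m, s in tokens) != label.replace("−", "-"):
        raise ValueError(f"cannot parse phenotype label {label!r}")
    out = []
    for marker, sign in tokens:
        marker = marker.upper()
        if marker not in KNOWN_MARKERS:
            raise ValueError(f"unknown marker {marker!r} in phenotype {label!r}")
        out.append((marker, sign == "+"))
    return out


def filter_cores(
    cores: pd.DataFrame, min_tumor_fraction: float = MIN_TUMOR_FRACTION
) -> pd.DataFrame:
    """Keep cores whose malignant-epithelial-cell fraction is >= the threshold.

    The boundary is inclusive (a core at exactly 50% tumor cells is retained).
    Idempotent; the number of excluded cores is logged and attached as
    ``result.attrs["n_removed"]``.
    """
    kept = cores[cores["tumor_cell_fraction"] >= min_tumor_fraction].copy()
    n_removed = len(cores) - len(kept)
    kept.attrs["n_removed"] = n_removed
    if n_removed:
        logger.info(
            "filter_cores: excluded %d of %d cores below %.0f%% tumor cells",
            n_removed,
            len(cores),
            100 * min_tumor_fraction,
        )
    return kept.reset_index(drop=True)


def core_immunoreactivity(positive: int, negative: int) -> float:
    """Percentage immunoreactivity of one core: 100 * pos / (pos + neg)."""
    if positive < 0 or negative < 0:
        raise ValueError("cell counts must be nonnegative")
    if positive + negative == 0:
        raise UndefinedStatisticError("core with zero scored cells")
    return 100.0 * positive / (positive + negative)


def case_density(cores: pd.DataFrame, case_id: str, marker: str) -> float:
    """Per-case density: unweighted mean immunoreactivity over the case's
    retained cores for one marker.

    Raises :class:`UndefinedStatisticError` when the case has no retained core
    for the marker — such cases are excluded from downstream statistics, not
    imputed.
    """
    sel = cores[(cores["case_id"] == case_id) & (cores["marker"] == marker)]
    if len(sel) == 0:
        raise UndefinedStatisticError(
            f"no retained cores for case {case_id!r}, marker {marker!r}"
        )
    pct = [
        core_immunoreactivity(int(p), int(n))
        for p, n in zip(sel["positive_cells"], sel["negative_cells"])
    ]
    return float(np.mean(pct))


def mif_density(
    cells: pd.DataFrame,
    phenotype: str,
    compartment: str = "total",
    *,
    method: str = "pooled",
) -> float:
    """Percent of nucleated cells in a compartment matching a phenotype.

    ``compartment`` is ``"tumor"``, ``"stroma"`` or ``"total"`` (both pooled).
    ``method="pooled"`` (default) computes a single ratio over all cells;
    ``method="per_field"`` averages the per-field percentages instead. Warns
    when the table has 10 or fewer distinct fields.
    """
    if compartment not in ("tumor", "stroma", "total"):
        raise ValueError(f"compartment must be tumor|stroma|total, got {compartment!r}")
    if "field_id" in cells.columns and cells["field_id"].nunique() <= 10:
        warnings.warn(
            "density computed from 10 or fewer fields; the acquisition "
            "convention is more than 10 fields per slide",
            UserWarning,
            stacklevel=2,
        )
    sub = cells if compartment == "total" else cells[cells["compartment"] == compartment]
    if len(sub) == 0:
        raise UndefinedStatisticError(f"no cells in compartment {compartment!r}")
    match = np.ones(len(sub), dtype=bool)
    for marker, positive in parse_phenotype(phenotype):
        if marker not in sub.columns:
            raise ValueError(f"cell table has no column for marker {marker!r}")
        flags = sub[marker].to_numpy(dtype=bool)
        match &= flags if positive else ~flags
    if method == "pooled":
        return 100.0 * float(match.sum()) / len(sub)
    if method == "per_field":
        frame = pd.DataFrame({"field_id": sub["field_id"].to_numpy(), "match": match})
        per_field = frame.groupby("field_id")["match"].mean()
        return 100.0 * float(per_field.mean())
    raise ValueError(f"method must be 'pooled' or 'per_field', got {method!r}")


def log2p1(density: float) -> float:
    """Figure-scale transform ``log2(density + 1)``; defined for density >= 0."""
    if density < 0:
        raise ValueError(f"density must be >= 0, got {density}")
    return float(np.log2(density + 1.0))


def paired_delta(pre: DensityRecord, post: DensityRecord) -> float:
    """Post-minus-pre density change for one sample/marker/compartment."""
    if (pre.sample_id, pre.marker, pre.compartment) != (
        post.sample_id,
        post.marker,
        post.compartment,
    ):
        raise PairingError(
            f"records are not a pre/post pair: {pre.sample_id}/{pre.marker}/"
            f"{pre.compartment} vs {post.sample_id}/{post.marker}/{post.compartment}"
        )
    return post.density - pre.density


def density_table(
    cells: pd.DataFrame,
    phenotypes: list[str],
    sample_id: str,
    timepoint: str,
    compartments: tuple[str, ...] = ("tumor", "stroma", "total"),
    *,
    method: str = "pooled",
) -> pd.DataFrame:
    """Long-format density table for one sample's cell table.

    Columns: sample_id, timepoint, marker, compartment, density, density_log2.
    Compartments with no cells are silently omitted (flagged by absence).
    """
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for phenotype in phenotypes:
            for compartment in compartments:
                try:
                    d = mif_density(cells, phenotype, compartment, method=method)
                except UndefinedStatisticError:
                    continue
                rows.append(
                    {
                        "sample_id": sample_id,
                        "timepoint": timepoint,
                        "marker": phenotype,
                        "compartment": compartment,
                        "density": d,
                        "density_log2": log2p1(d),
                    }
                )
    return pd.DataFrame(rows)
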