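"""Synthetic paired pre/post-chemotherapy cohorts.

Nothing downstream depends on real patient data: this module simulates the
statistical structure the analysis assumes —

* clone-rank abundance decaying approximately as a power law (truncated Zipf
  over ranks, reads drawn multinomially),
* a post-treatment perturbation that eliminates the most-expanded clones,
  lowers sequencing depth and admits new low-abundance clones, so that the
  post sample has fewer total reads but more unique clonotypes and higher
  evenness than its paired pre sample,
* per-cell multiplex-immunofluorescence phenotype tables split into tumor-nest
  and stromal compartments,
* per-core immunohistochemistry counts with a malignant-epithelial-cell
  fraction (tissue-microarray triplicates),
* clinical covariates: regimen, tumor regression grade (responder = TRG 0/1),
  paired tumor-mutation-burden counts, neoantigen counts coupled to TMB, and
  exponential survival whose log-hazard includes a CD8-density coefficient,
  with administrative censoring at a fixed horizon.

All randomness flows from a single integer seed through named per-table
streams, so any one table can be regenerated independently and identical
config + seed yields byte-identical tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import EmptyRepertoireError, InvalidConfigurationError

__all__ = [
    "CohortConfig",
    "SimulatedCohort",
    "generate_repertoire",
    "perturb_post_treatment",
    "generate_cell_table",
    "generate_core_table",
    "generate_clinical",
    "generate_cohort",
]

MIF_MARKERS: tuple[str, ...] = ("CD3", "CD4", "CD8", "FOXP3", "PDL1")

# named sub-streams so tables can be regenerated independently of each other
_STREAMS = {
    "repertoire": 1,
    "perturb": 2,
    "cells": 3,
    "cores": 4,
    "clinical": 5,
    "effects": 6,
}


def _rng(seed: int, stream: str, *extra: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream], *map(int, extra)])


def _junction(i: int) -> str:
    """Deterministic pseudo-CDR3 amino-acid string for clone index ``i``."""
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    body = []
    j = i
    for _ in range(6):
        body.append(alphabet[j % 20])
        j //= 20
    return "CASS" + "".join(reversed(body)) + "EQYF"


# --------------------------------------------------------------------------
# effect sizes: marker -> (pre-treatment mean density %, additive shift after
# treatment, additive shift in responders). Defaults emulate the qualitative
# cohort pattern: regulatory FOXP3+ cells drop after chemotherapy and are
# richer pre-treatment in responders; cytotoxic CD8+ cells rise.
# --------------------------------------------------------------------------
def default_effect_sizes() -> dict[str, tuple[float, float, float]]:
    return {
        "CD3": (20.0, -3.0, 0.0),
        "CD4": (12.0, -2.0, 0.0),
        "CD8": (8.0, 4.0, 2.0),
        "FOXP3": (10.0, -4.0, 3.0),
        "PDL1": (5.0, -1.0, 0.0),
    }


@dataclass
class CohortConfig:
    """All knobs of the simulated paired cohort.

    Repertoire parameters follow the study design of a paired biopsy/resection
    cohort of 30 patients; density effect sizes are percent-of-nucleated-cells
    shifts; survival is exponential in months with administrative censoring.
    """

    n_patients: int = 30
    n_clones_pre: int = 1000
    zipf_exponent: float = 1.5
    reads_pre: int = 50000
    depth_factor_post: float = 0.7
    top_elimination_fraction: float = 0.01
    novel_influx: int = 200
    responder_fraction: float = 0.5
    regimen_split: float = 0.5  # fraction XELOX (rest SOX)
    effect_sizes: dict[str, tuple[float, float, float]] = field(
        default_factory=default_effect_sizes
    )
    seed: int = 0
    # cell/core table geometry
    n_fields: int = 12
    cells_per_field: int = 300
    cores_per_case: int = 3
    # nuisance scales
    density_sd: float = 3.0  # patient-to-patient density spread (percent)
    tmb_mean: float = 80.0
    tmb_shift: float = 20.0  # mean post - pre TMB increment
    neoantigen_rate: float = 0.1  # neoantigens per mutation
    cd8_log_hazard: float = -0.03  # per percent CD8 density
    base_hazard: float = 0.03  # events per month at CD8 density 0... scaled below
    censor_horizon: float = 60.0  # months of administrative follow-up

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_clones_pre < 1 or self.reads_pre < 1:
            raise InvalidConfigurationError("counts must be positive")
        if self.zipf_exponent < 0:
            raise InvalidConfigurationError("zipf_exponent must be >= 0")
        if not (0 < self.depth_factor_post <= 1):
            raise InvalidConfigurationError("depth_factor_post must be in (0, 1]")
        for name in ("top_elimination_fraction", "responder_fraction", "regimen_split"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise InvalidConfigurationError(f"{name} must be in [0, 1]")
        if self.novel_influx < 0:
            raise InvalidConfigurationError("novel_influx must be >= 0")


# --------------------------------------------------------------------------
# repertoires
# --------------------------------------------------------------------------
def generate_repertoire(
    n_clones: int,
    zipf_exponent: float,
    total_reads: int,
    seed: int,
    *,
    rng: np.random.Generator | None = None,
    id_prefix: str = "C",
) -> pd.DataFrame:
    """Draw a clonotype table whose rank-abundance follows a truncated Zipf law.

    Clone r (r = 1..n_clones) has sampling probability proportional to
    r**(-zipf_exponent); read counts are multinomial at depth ``total_reads``.
    Any clone drawn with zero reads is re-seeded with one read taken from the
    largest clone(s), so exactly ``n_clones`` clonotypes appear and counts sum
    exactly to ``total_reads``. Exponent 0 is uniform sampling.
    """
    if n_clones < 1:
        raise InvalidConfigurationError("n_clones must be >= 1")
    if total_reads < n_clones:
        raise InvalidConfigurationError(
            f"total_reads ({total_reads}) must be >= n_clones ({n_clones})"
        )
    if zipf_exponent < 0:
        raise InvalidConfigurationError("zipf_exponent must be >= 0")
    if rng is None:
        rng = _rng(seed, "repertoire")
    ranks = np.arange(1, n_clones + 1, dtype=float)
    probs = ranks ** (-float(zipf_exponent))
    probs /= probs.sum()
    counts = rng.multinomial(total_reads, probs)

    zero = np.flatnonzero(counts == 0)
    if zero.size:
        # steal one read per empty clone from the richest clones, never
        # driving a donor below one read; feasible because total >= n
        need = int(zero.size)
        for j in np.argsort(-counts, kind="stable"):
            if need == 0:
                break
            give = min(int(counts[j]) - 1, need)
            if give <= 0:
                break
            counts[j] -= give
            need -= give
        counts[zero] = 1

    return pd.DataFrame(
        {
            "clonotype_id": [f"{id_prefix}{i:06d}" for i in range(1, n_clones + 1)],
            "junction_aa": [_junction(i) for i in range(1, n_clones + 1)],
            "count": counts.astype(int),
        }
    )


def perturb_post_treatment(
    pre: pd.DataFrame,
    top_elimination_fraction: float,
    novel_influx: int,
    depth_factor: float,
    seed: int,
    *,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Post-treatment repertoire: eliminate expanded clones, shrink depth,
    admit novel clones.

    The ``ceil(top_elimination_fraction * unique)`` highest-count clones are
    removed; ``novel_influx`` new clonotypes enter at the minimum surviving
    clone frequency; reads are resampled multinomially to
    ``round(depth_factor * total)``. Clones drawn with zero reads at the lower
    depth drop out (no re-seeding — losing marginal clones to shallower
    sequencing is part of what the perturbation emulates).
    """
    if pre is None or len(pre) == 0:
        raise EmptyRepertoireError("pre-treatment repertoire is empty")
    if not (0 <= top_elimination_fraction <= 1):
        raise InvalidConfigurationError("top_elimination_fraction must be in [0, 1]")
    if not (0 < depth_factor <= 1):
        raise InvalidConfigurationError("depth_factor must be in (0, 1]")
    if novel_influx < 0:
        raise InvalidConfigurationError("novel_influx must be >= 0")
    if top_elimination_fraction == 0 and novel_influx == 0 and depth_factor == 1:
        # identity perturbation: with every treatment parameter at its null
        # value the post sample is the pre sample. (A resample at full depth
        # would still drop singletons and so would not be a null treatment.)
        return pre.copy()
    if rng is None:
        rng = _rng(seed, "perturb")

    n_unique = len(pre)
    n_elim = math.ceil(top_elimination_fraction * n_unique)
    ordered = pre.sort_values(
        ["count", "clonotype_id"], ascending=[False, True], kind="mergesort"
    )
    survivors = ordered.iloc[n_elim:]
    if len(survivors) == 0 and novel_influx == 0:
        raise EmptyRepertoireError(
            "perturbation eliminated every clone and no novel clones enter"
        )

    weights = survivors["count"].to_numpy(dtype=float)
    min_w = weights.min() if weights.size else 1.0
    ids = list(survivors["clonotype_id"])
    junctions = list(survivors.get("junction_aa", pd.Series(ids, index=survivors.index)))
    for i in range(1, novel_influx + 1):
        ids.append(f"N{i:06d}")
        junctions.append(_junction(10_000_000 + i))
    weights = np.concatenate([weights, np.full(novel_influx, min_w)])
    probs = weights / weights.sum()

    total_post = max(1, int(round(depth_factor * float(pre["count"].sum()))))
    counts = rng.multinomial(total_post, probs)
    keep = counts > 0
    post = pd.DataFrame(
        {
            "clonotype_id": np.asarray(ids, dtype=object)[keep],
            "junction_aa": np.asarray(junctions, dtype=object)[keep],
            "count": counts[keep].astype(int),
        }
    )
    return post.reset_index(drop=True)


# --------------------------------------------------------------------------
# cell and core tables
# --------------------------------------------------------------------------
def generate_cell_table(
    n_fields: int,
    cells_per_field: int,
    phenotype_fractions: Mapping[tuple[str, str], float],
    seed: int,
    *,
    stroma_fraction: float = 0.5,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-cell phenotype table with tumor/stroma compartment labels.

    ``phenotype_fractions`` maps (phenotype-combination, compartment) — e.g.
    ``("FOXP3+CD3+", "stroma")`` — to the fraction of that compartment's
    nucleated cells carrying exactly that combination; fractions within a
    compartment must sum to <= 1 (the remainder are marker-negative cells).
    Emits a warning below 11 fields, mirroring the more-than-10-fields-per-
    slide acquisition convention, but still produces the table.
    """
    if n_fields < 1 or cells_per_field < 1:
        raise InvalidConfigurationError("n_fields and cells_per_field must be >= 1")
    if n_fields <= 10:
        warnings.warn(
            f"only {n_fields} fields; density estimates are conventionally based "
            "on more than 10 fields per slide",
            UserWarning,
            stacklevel=2,
        )
    from .density import parse_phenotype  # local import to avoid a cycle

    by_compartment: dict[str, list[tuple[str, float]]] = {"tumor": [], "stroma": []}
    for (combo, compartment), frac in phenotype_fractions.items():
        if compartment not in by_compartment:
            raise InvalidConfigurationError(
                f"compartment must be 'tumor' or 'stroma', got {compartment!r}"
            )
        if not (0 <= frac <= 1):
            raise InvalidConfigurationError("phenotype fractions must be in [0, 1]")
        parse_phenotype(combo)  # validates marker names / syntax
        by_compartment[compartment].append((combo, float(frac)))
    for compartment, combos in by_compartment.items():
        s = sum(f for _, f in combos)
        if s > 1 + 1e-12:
            raise InvalidConfigurationError(
                f"phenotype fractions in {compartment} sum to {s:.3f} > 1"
            )

    if rng is None:
        rng = _rng(seed, "cells")
    n_cells = n_fields * cells_per_field
    field_id = np.repeat(np.arange(1, n_fields + 1), cells_per_field)
    compartment = np.where(
        rng.random(n_cells) < stroma_fraction, "stroma", "tumor"
    )

    flags = {m: np.zeros(n_cells, dtype=bool) for m in MIF_MARKERS}
    for comp, combos in by_compartment.items():
        idx = np.flatnonzero(compartment == comp)
        if idx.size == 0 or not combos:
            continue
        probs = np.array([f for _, f in combos] + [1 - sum(f for _, f in combos)])
        probs = np.clip(probs, 0, None)
        probs /= probs.sum()
        assignment = rng.choice(len(probs), size=idx.size, p=probs)
        for k, (combo, _) in enumerate(combos):
            cells_k = idx[assignment == k]
            for marker, positive in parse_phenotype(combo):
                if positive:
                    flags[marker][cells_k] = True

    table = pd.DataFrame(
        {
            "cell_id": [f"cell{n:07d}" for n in range(1, n_cells + 1)],
            "field_id": field_id,
            "compartment": compartment,
        }
    )
    for m in MIF_MARKERS:
        table[m] = flags[m]
    return table


def generate_core_table(
    n_cases: int,
    cores_per_case: int,
    tumor_fraction_beta: tuple[float, float],
    positivity_rate: float,
    seed: int,
    *,
    marker: str = "CD3",
    cells_per_core: int = 1000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-core immunohistochemistry counts for a tissue-microarray design.

    Each case contributes ``cores_per_case`` cores (three in the standard TMA
    layout); per core the malignant-epithelial-cell fraction is Beta
    distributed and positive/negative immune-cell counts are binomial at
    ``positivity_rate``.
    """
    if n_cases < 1 or cores_per_case < 1:
        raise InvalidConfigurationError("n_cases and cores_per_case must be >= 1")
    if not (0 <= positivity_rate <= 1):
        raise InvalidConfigurationError("positivity_rate must be in [0, 1]")
    a, b = tumor_fraction_beta
    if a <= 0 or b <= 0:
        raise InvalidConfigurationError("Beta parameters must be > 0")
    if rng is None:
        rng = _rng(seed, "cores")
    rows = []
    for case in range(1, n_cases + 1):
        for core in range(1, cores_per_case + 1):
            n_cells = max(1, int(rng.poisson(cells_per_core)))
            positive = int(rng.binomial(n_cells, positivity_rate))
            rows.append(
                {
                    "case_id": f"case{case:04d}",
                    "core_id": f"case{case:04d}_core{core}",
                    "marker": marker,
                    "positive_cells": positive,
                    "negative_cells": n_cells - positive,
                    "tumor_cell_fraction": float(rng.beta(a, b)),
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# clinical covariates and survival
# --------------------------------------------------------------------------
def _patient_densities(
    config: CohortConfig, responder: np.ndarray, rng: np.random.Generator
) -> dict[str, dict[str, np.ndarray]]:
    """Per-patient target density (percent) for each marker and timepoint."""
    n = config.n_patients
    out: dict[str, dict[str, np.ndarray]] = {}
    for marker, (pre_mean, post_shift, resp_shift) in config.effect_sizes.items():
        base = rng.normal(pre_mean, config.density_sd, size=n) + resp_shift * responder
        pre = np.clip(base, 0.0, 100.0)
        post = np.clip(base + post_shift + rng.normal(0, config.density_sd, size=n), 0.0, 100.0)
        out[marker] = {"pre": pre, "post": post}
    return out


def generate_clinical(
    config: CohortConfig,
    *,
    densities: dict[str, dict[str, np.ndarray]] | None = None,
) -> pd.DataFrame:
    """Clinical table: one row per patient per timepoint.

    TRG is 0/1 for responders and 2/3 otherwise; TMB increases after treatment
    by ``tmb_shift`` mutations on average; neoantigen counts are binomial in
    TMB (positive coupling); overall survival is exponential with log-hazard
    ``cd8_log_hazard`` per percent of post-treatment CD8 density, censored
    administratively at ``censor_horizon`` months.
    """
    rng = _rng(config.seed, "clinical")
    n = config.n_patients
    responder = rng.random(n) < config.responder_fraction
    trg = np.where(responder, rng.integers(0, 2, size=n), rng.integers(2, 4, size=n))
    regimen = np.where(rng.random(n) < config.regimen_split, "XELOX", "SOX")

    if densities is None:
        densities = _patient_densities(
            config, responder.astype(float), _rng(config.seed, "effects")
        )
    cd8_post = densities.get("CD8", {"post": np.zeros(n)})["post"]

    tmb_pre = rng.poisson(config.tmb_mean, size=n)
    tmb_post = rng.poisson(np.maximum(tmb_pre + config.tmb_shift, 1.0))
    neo_pre = rng.binomial(tmb_pre, config.neoantigen_rate)
    neo_post = rng.binomial(tmb_post, config.neoantigen_rate)

    # exponential survival; baseline scaled so the cohort median is realistic
    # (~32 months) at the expected CD8 density rather than at density zero
    if "CD8" in config.effect_sizes:
        mean_cd8 = config.effect_sizes["CD8"][0] + config.effect_sizes["CD8"][1]
    else:
        mean_cd8 = 0.0
    lam0 = config.base_hazard * math.exp(-config.cd8_log_hazard * mean_cd8)
    hazard = lam0 * np.exp(config.cd8_log_hazard * cd8_post)
    t = rng.exponential(1.0 / hazard)
    event = t <= config.censor_horizon
    os_months = np.minimum(t, config.censor_horizon)

    rows = []
    for tp in ("pre", "post"):
        tmb = tmb_pre if tp == "pre" else tmb_post
        neo = neo_pre if tp == "pre" else neo_post
        for i in range(n):
            rows.append(
                {
                    "patient_id": f"P{i + 1:03d}",
                    "timepoint": tp,
                    "regimen": regimen[i],
                    "trg": int(trg[i]),
                    "responder": bool(responder[i]),
                    "tmb": int(tmb[i]),
                    "neoantigen": int(neo[i]),
                    "cd8_density": float(cd8_post[i]),
                    "os_months": float(os_months[i]),
                    "os_event": bool(event[i]),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class SimulatedCohort:
    """All tables of one simulated paired cohort."""

    config: CohortConfig
    clinical: pd.DataFrame
    repertoires: dict[tuple[str, str], pd.DataFrame]  # (patient_id, timepoint) -> table
    cells: dict[tuple[str, str], pd.DataFrame]
    densities: dict[str, dict[str, np.ndarray]]


def generate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Simulate the full paired cohort: repertoires, cell tables, clinical."""
    n = config.n_patients
    rng_clin = _rng(config.seed, "clinical")
    responder = rng_clin.random(n) < config.responder_fraction  # same stream order as generate_clinical
    densities = _patient_densities(
        config, responder.astype(float), _rng(config.seed, "effects")
    )
    clinical = generate_clinical(config, densities=densities)

    repertoires: dict[tuple[str, str], pd.DataFrame] = {}
    cells: dict[tuple[str, str], pd.DataFrame] = {}
    for i in range(n):
        pid = f"P{i + 1:03d}"
        pre = generate_repertoire(
            config.n_clones_pre,
            config.zipf_exponent,
            config.reads_pre,
            config.seed,
            rng=_rng(config.seed, "repertoire", i),
        )
        post = perturb_post_treatment(
            pre,
            config.top_elimination_fraction,
            config.novel_influx,
            config.depth_factor_post,
            config.seed,
            rng=_rng(config.seed, "perturb", i),
        )
        repertoires[(pid, "pre")] = pre
        repertoires[(pid, "post")] = post

        for tp_idx, tp in enumerate(("pre", "post")):
            fractions: dict[tuple[str, str], float] = {}
            for marker in config.effect_sizes:
                target = float(densities[marker][tp][i]) / 100.0
                for comp in ("tumor", "stroma"):
                    fractions[(f"{marker}+", comp)] = target
            # rescale if a compartment's single-marker fractions exceed 1
            for comp in ("tumor", "stroma"):
                s = sum(v for (c, cc), v in fractions.items() if cc == comp)
                if s > 1:
                    for key in list(fractions):
                        if key[1] == comp:
                            fractions[key] /= s
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                cells[(pid, tp)] = generate_cell_table(
                    config.n_fields,
                    config.cells_per_field,
                    fractions,
                    config.seed,
                    rng=_rng(config.seed, "cells", i, tp_idx),
                )
    return SimulatedCohort(
        config=config,
        clinical=clinical,
        repertoires=repertoires,
        cells=cells,
        densities=densities,
    )
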