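"""Synthetic spine maps, trait tables and nutrition tables.

The field study behind this package digitized spine positions from
photographs and measured traits in a botanical garden; none of those raw
coordinates are distributed.  This module generates inputs with the same
statistical structure so that every downstream stage (debarking and climbing
simulation, syndrome clustering, group comparisons) is fully testable.

Four syndrome presets carry the published per-syndrome summary values
(trunk spine density and mean spine length) and the arrangement that
characterizes each syndrome:

========  ============  ============  ===========  =================
syndrome  density /m^2  mean len cm   arrangement  spine type
========  ============  ============  ===========  =================
prickly   2500          2.2           random       cork/prickle
thorny    1800          8.9           phyllotaxic  thorn
crown     800           2.7           phyllotaxic  thorn/stipule
liana     1300          2.0           random       prickle/leaf
========  ============  ============  ===========  =================

Random maps are homogeneous Poisson point processes on the cylinder surface
(the measured maps were not modelled, so the minimal-assumption stationary
process is used).  Phyllotaxic maps restrict spine bases to node rows spaced
``node_spacing_cm`` apart, with ``cluster_size`` spines per occupied node
(Neyman-Scott style clumping within rows, jittered in x only so that node-row
membership stays exact).  Spine lengths are i.i.d. log-normal.

All generators are deterministic functions of an explicit integer seed; there
is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .geometry import SpineMap, TrunkSurface

__all__ = [
    "BudgetError",
    "SyndromeParams",
    "NutritionEffects",
    "SYNDROMES",
    "syndrome_presets",
    "generate_spine_map",
    "generate_trait_table",
    "generate_nutrition_table",
]

SYNDROMES = ("prickly", "thorny", "crown", "liana")

#: hard cap on the expected spine count of a single generated map
MAX_EXPECTED_COUNT = 1_000_000


class BudgetError(ValueError):
    """Requested simulation size exceeds the generator budget."""


@dataclass(frozen=True)
class SyndromeParams:
    """Generative parameters for one trunk-spine syndrome.

    ``length_sd_cm`` defaults to 30 % of the mean (right-skewed spine length
    distributions); ``node_spacing_cm`` is the internode-scale distance
    between node rows for phyllotaxic arrangements; ``cluster_size`` is the
    number of spines recruited per occupied node; ``curved_fraction`` is the
    fraction of spines with curved shape (metadata for trait generation).
    """

    name: str
    density_per_m2: float
    length_mean_cm: float
    length_sd_cm: float
    arrangement: str  # {"random", "phyllotaxic"}
    cluster_size: int = 1
    node_spacing_cm: float = 2.0
    curved_fraction: float = 0.0
    cluster_jitter_cm: float = 0.5

    def __post_init__(self) -> None:
        if not self.density_per_m2 >= 0:
            raise ValueError("density_per_m2 must be non-negative")
        if self.length_mean_cm <= 0 or self.length_sd_cm < 0:
            raise ValueError("length parameters must yield positive lengths")
        if self.arrangement not in ("random", "phyllotaxic"):
            raise ValueError(f"unknown arrangement {self.arrangement!r}")
        if self.arrangement == "phyllotaxic" and not self.node_spacing_cm > 0:
            raise ValueError("phyllotaxic arrangement requires node_spacing_cm > 0")
        if self.cluster_size < 1:
            raise ValueError("cluster_size must be a positive integer")


def _preset(name, density, length, arrangement, cluster_size=1, curved=0.0):
    return SyndromeParams(
        name=name,
        density_per_m2=density,
        length_mean_cm=length,
        length_sd_cm=0.3 * length,
        arrangement=arrangement,
        cluster_size=cluster_size,
        node_spacing_cm=2.0,
        curved_fraction=curved,
    )


_PRESETS: dict[str, SyndromeParams] = {
    # published per-syndrome means: density (spines/m^2) and spine length (cm)
    "prickly": _preset("prickly", 2500.0, 2.2, "random"),
    "thorny": _preset("thorny", 1800.0, 8.9, "phyllotaxic", cluster_size=1),
    "crown": _preset("crown", 800.0, 2.7, "phyllotaxic", cluster_size=2),
    "liana": _preset("liana", 1300.0, 2.0, "random", curved=1.0),
}


def syndrome_presets() -> dict[str, SyndromeParams]:
    """Return the four syndrome presets (fresh dict; presets are frozen)."""
    return dict(_PRESETS)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and sd."""
    if sd == 0:
        return np.log(mean), 0.0
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def generate_spine_map(
    params: SyndromeParams,
    surface: TrunkSurface,
    seed: int,
    species_id: str | None = None,
) -> SpineMap:
    """Draw one synthetic spine map for a syndrome on a trunk surface.

    ``arrangement="random"`` gives a homogeneous Poisson process with the
    preset intensity; ``"phyllotaxic"`` places clusters of ``cluster_size``
    spines on node rows (y an exact multiple of ``node_spacing_cm``), with
    the number of clusters Poisson so the expected total count still equals
    ``density_per_m2 * area``.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    expected = params.density_per_m2 * surface.area_m2
    if expected > MAX_EXPECTED_COUNT:
        raise BudgetError(
            f"expected spine count {expected:.3g} exceeds {MAX_EXPECTED_COUNT}"
        )
    C, H = surface.circumference_cm, surface.height_cm

    if params.arrangement == "random":
        n = rng.poisson(expected)
        x = rng.uniform(0.0, C, size=n)
        y = rng.uniform(0.0, H, size=n)
    else:
        rows = np.arange(0.0, H + 1e-9, params.node_spacing_cm)
        n_clusters = rng.poisson(expected / params.cluster_size)
        row_idx = rng.integers(0, len(rows), size=n_clusters)
        centers = rng.uniform(0.0, C, size=n_clusters)
        y = np.repeat(rows[row_idx], params.cluster_size)
        x = np.repeat(centers, params.cluster_size)
        if params.cluster_size > 1:
            x = (x + rng.normal(0.0, params.cluster_jitter_cm, size=x.size)) % C
        n = x.size

    mu, sigma = _lognormal_params(params.length_mean_cm, params.length_sd_cm)
    lengths = rng.lognormal(mu, sigma, size=n)
    return SpineMap(
        surface, x, y, lengths,
        species_id=species_id or f"{params.name}_synth_{seed}",
        syndrome=params.name,
    )


# -- trait tables --------------------------------------------------------------

# Syndrome-typical categorical trait states, following the published syndrome
# descriptions: prickly = late-emerging maintained cork spines renewed over
# the whole trunk height; thorny = long nodal thorns recruited after leaf
# fall, below 2-3 m, directionally mixed; crown = short-lived nodal spines
# produced with leaves; liana = curved spines on non-self-supporting stems
# along the entire trunk.
_TRAIT_PROFILES: dict[str, dict[str, str]] = {
    "prickly": dict(
        main_stem_habit="self-supporting", spine_shape="straight",
        branching="unbranched", orientation="homogeneous", arrangement="random",
        emergence_timing="late", pruning="maintained", renewal="renewal",
        vertical_distribution="extended", spine_type="cork",
    ),
    "thorny": dict(
        main_stem_habit="self-supporting", spine_shape="straightened",
        branching="branched", orientation="mixed", arrangement="phyllotaxic",
        emergence_timing="immediate", pruning="maintained", renewal="renewal",
        vertical_distribution="restricted", spine_type="thorn",
    ),
    "crown": dict(
        main_stem_habit="self-supporting", spine_shape="straight",
        branching="unbranched", orientation="homogeneous",
        arrangement="phyllotaxic", emergence_timing="immediate",
        pruning="pruned", renewal="no renewal",
        vertical_distribution="restricted", spine_type="thorn",
    ),
    "liana": dict(
        main_stem_habit="non-self-supporting", spine_shape="curved",
        branching="unbranched", orientation="homogeneous", arrangement="random",
        emergence_timing="immediate", pruning="maintained",
        renewal="no renewal", vertical_distribution="extended",
        spine_type="prickle",
    ),
}

_TRAIT_STATES: dict[str, tuple[str, ...]] = {
    "main_stem_habit": ("self-supporting", "non-self-supporting"),
    "spine_shape": ("curved", "straight", "straightened"),
    "branching": ("branched", "unbranched"),
    "orientation": ("homogeneous", "mixed"),
    "arrangement": ("phyllotaxic", "random"),
    "emergence_timing": ("immediate", "late"),
    "pruning": ("maintained", "pruned"),
    "renewal": ("renewal", "no renewal"),
    "vertical_distribution": ("extended", "restricted"),
}


def generate_trait_table(
    n_per_syndrome: int,
    seed: int,
    noise: float = 0.05,
) -> pd.DataFrame:
    """Synthetic species x trait table with known syndrome membership.

    One row per species, carrying the 12 morphological variables (continuous
    density in spines/cm^2 and length in cm drawn log-normally around the
    syndrome means; categorical states from the syndrome profile, each flipped
    to a random other state with probability ``noise``) plus ``species_id``
    and the true ``syndrome`` label.  ``spine_type`` is metadata only and
    never enters clustering.
    """
    if n_per_syndrome < 1:
        raise ValueError("n_per_syndrome must be >= 1")
    if not 0 <= noise <= 1:
        raise ValueError("noise must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for syndrome in SYNDROMES:
        params = _PRESETS[syndrome]
        profile = _TRAIT_PROFILES[syndrome]
        dmu, dsig = _lognormal_params(params.density_per_m2 / 1e4, 0.3 * params.density_per_m2 / 1e4)
        lmu, lsig = _lognormal_params(params.length_mean_cm, params.length_sd_cm)
        for i in range(n_per_syndrome):
            row = {
                "species_id": f"{syndrome}_{i:02d}",
                "syndrome": syndrome,
                "spine_density": float(rng.lognormal(dmu, dsig)),
                "spine_length": float(rng.lognormal(lmu, lsig)),
                "spine_type": profile["spine_type"],
            }
            for trait, states in _TRAIT_STATES.items():
                state = profile[trait]
                if noise > 0 and rng.uniform() < noise:
                    others = [s for s in states if s != state]
                    state = others[rng.integers(0, len(others))]
                row[trait] = state
            rows.append(row)
    return pd.DataFrame(rows)


# -- nutrition tables ----------------------------------------------------------

RESPONSES = ("nitrogen", "total_phenols", "inner_bark_thickness")
GROUPS = SYNDROMES + ("non_spiny",)
MONTHS = ("2017-05", "2019-03")


@dataclass(frozen=True)
class NutritionEffects:
    """Log-scale generative model for the nutrition table.

    ``log(response) = log(baseline) + log(group multiplier) + species effect
    + month effect + residual`` with the three random terms Gaussian on the
    log scale (log-normal errors).  Defaults: leaf/bark nitrogen around
    20 mg/g, total phenols around 50 assay units, inner bark 3 mm thick, with
    the prickly syndrome's inner bark twice as thick as the others (the
    published headline contrast).
    """

    baselines: Mapping[str, float] = field(
        default_factory=lambda: {
            "nitrogen": 20.0,            # mg/g dry matter
            "total_phenols": 50.0,       # assay units (gallic-acid equiv.)
            "inner_bark_thickness": 3.0, # mm
        }
    )
    group_effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {"prickly": {"inner_bark_thickness": 2.0}}
    )
    species_sd: float = 0.20
    month_sd: float = 0.10
    residual_sd: float = 0.15

    def __post_init__(self) -> None:
        if min(self.baselines.values()) <= 0:
            raise ValueError("baselines must be positive")
        if min(self.species_sd, self.month_sd, self.residual_sd) < 0:
            raise ValueError("random-effect SDs must be non-negative")

    def multiplier(self, group: str, response: str) -> float:
        return float(self.group_effects.get(group, {}).get(response, 1.0))


def generate_nutrition_table(
    effects: NutritionEffects,
    n_species_per_group: int,
    n_replicates: int,
    seed: int,
    groups: tuple[str, ...] = GROUPS,
) -> pd.DataFrame:
    """Synthetic nutrition measurements for mixed-model comparisons.

    One row per (species, organ, month, replicate).  Nitrogen and total
    phenols are measured on both leaf and inner bark; inner-bark thickness
    only on bark rows.  Replicate counts per (species, month) are
    ``n_replicates`` capped at 6 (one to six individuals per species).
    Deterministic given ``seed``.
    """
    if n_species_per_group < 1 or n_replicates < 1:
        raise ValueError("n_species_per_group and n_replicates must be >= 1")
    n_replicates = min(n_replicates, 6)
    rng = np.random.default_rng(seed)
    month_eff = {m: rng.normal(0.0, effects.month_sd) for m in MONTHS}
    rows = []
    for group in groups:
        for i in range(n_species_per_group):
            sp = f"{group}_sp{i:03d}"
            sp_eff = {r: rng.normal(0.0, effects.species_sd) for r in RESPONSES}
            for organ in ("leaf", "inner_bark"):
                for month in MONTHS:
                    for rep in range(n_replicates):
                        row = {
                            "species_id": sp, "group": group, "organ": organ,
                            "month": month, "replicate": rep,
                        }
                        for resp in RESPONSES:
                            if resp == "inner_bark_thickness" and organ != "inner_bark":
                                row[resp] = np.nan
                                continue
                            log_val = (
                                np.log(effects.baselines[resp])
                                + np.log(effects.multiplier(group, resp))
                                + sp_eff[resp]
                                + month_eff[month]
                                + rng.normal(0.0, effects.residual_sd)
                            )
                            row[resp] = float(np.exp(log_val))
                        rows.append(row)
    return pd.DataFrame(rows)
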