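"""Morphological trait encoding, syndrome clustering and ordination.

Twelve variables describe each spiny species: two continuous (trunk spine
density in spines/cm^2 and spine length in cm), nine categorical
(stem habit, spine shape, branching, orientation, arrangement, emergence
timing, pruning, renewal, vertical distribution) and ``spine_type``, which
records the anatomical origin of the spines and is kept as metadata only —
it never enters the clustering, to avoid confounding function with origin.

Encoding: continuous traits are natural-log transformed then min-max scaled
to [0, 1] (a degenerate, constant column maps to all zeros); binary traits
become 0/1 indicators; the three-state shape trait becomes three one-hot
columns (ordinal coding was rejected: "straightened" is not intermediate
between curved and straight in any stated sense).  Every variable therefore
occupies the same [0, 1] range and weighs equally.

Clustering uses Ward's minimum-variance agglomeration on Euclidean distances
of the full encoded matrix (scipy's ``ward``, i.e. the Ward.D2 convention —
stated because dendrogram heights differ between conventions), cut at
``n_clusters`` (4 follows the study design).  Per-variable contributions are
correlation ratios (eta^2 = between-cluster SS / total SS); ordination is the
principal-component decomposition of the centred matrix, equivalent to
principal coordinates of Euclidean distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "TraitRecord",
    "TraitMatrix",
    "TraitValidationError",
    "CONTINUOUS_TRAITS",
    "BINARY_TRAITS",
    "encode_and_scale",
    "cluster_syndromes",
    "correlation_ratio",
    "ordination",
    "read_trait_table",
]


class TraitValidationError(ValueError):
    """A trait value is missing, non-positive or not an allowed state."""


CONTINUOUS_TRAITS = ("spine_density", "spine_length")

# binary traits: (name, state coded 1, state coded 0)
BINARY_TRAITS = (
    ("main_stem_habit", "non-self-supporting", "self-supporting"),
    ("branching", "branched", "unbranched"),
    ("orientation", "mixed", "homogeneous"),
    ("arrangement", "phyllotaxic", "random"),
    ("emergence_timing", "late", "immediate"),
    ("pruning", "maintained", "pruned"),
    ("renewal", "renewal", "no renewal"),
    ("vertical_distribution", "extended", "restricted"),
)

SHAPE_STATES = ("curved", "straight", "straightened")

#: analysis variables in canonical order (spine_type is metadata, excluded)
VARIABLES = (
    "main_stem_habit", "spine_density", "spine_length", "spine_shape",
    "branching", "orientation", "arrangement", "emergence_timing",
    "pruning", "renewal", "vertical_distribution",
)


@dataclass(frozen=True)
class TraitRecord:
    """One species' morphological description."""

    species_id: str
    main_stem_habit: str
    spine_density: float  # spines per cm^2
    spine_length: float   # cm
    spine_shape: str
    branching: str
    orientation: str
    arrangement: str
    emergence_timing: str
    pruning: str
    renewal: str
    vertical_distribution: str
    spine_type: str = "thorn"  # metadata only


@dataclass
class TraitMatrix:
    """Species x encoded-variable matrix, all entries in [0, 1].

    ``encoding`` maps each analysis variable to the column names it occupies
    (one for scalars, three for the one-hot shape trait).
    """

    data: pd.DataFrame
    encoding: Mapping[str, tuple[str, ...]]

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def _to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    return pd.DataFrame([r.__dict__ for r in records])


def encode_and_scale(records: Iterable[TraitRecord] | pd.DataFrame) -> TraitMatrix:
    """Encode trait records to the [0, 1] numeric matrix used for clustering."""
    df = _to_frame(records)
    if len(df) < 2:
        raise TraitValidationError("need at least 2 species to encode and scale")
    if df["species_id"].duplicated().any():
        # keep rows but make the index unique for duplicated control species
        df = df.copy()
        df["species_id"] = [
            f"{s}#{i}" if dup else s
            for i, (s, dup) in enumerate(zip(df["species_id"],
                                             df["species_id"].duplicated(keep=False)))
        ]
    out = {}
    encoding: dict[str, tuple[str, ...]] = {}

    for trait in CONTINUOUS_TRAITS:
        vals = pd.to_numeric(df[trait], errors="coerce")
        if vals.isna().any() or (vals <= 0).any():
            bad = df["species_id"][vals.isna() | (vals <= 0)].tolist()
            raise TraitValidationError(
                f"{trait} must be positive and numeric; offending species: {bad}"
            )
        logged = np.log(vals.to_numpy(dtype=float))
        rng = logged.max() - logged.min()
        out[trait] = (logged - logged.min()) / rng if rng > 0 else np.zeros(len(df))
        encoding[trait] = (trait,)

    for trait, one_state, zero_state in BINARY_TRAITS:
        col = df[trait].astype(str)
        bad = ~col.isin([one_state, zero_state])
        if bad.any():
            raise TraitValidationError(
                f"{trait} has states outside {{{one_state!r}, {zero_state!r}}}: "
                f"{sorted(col[bad].unique())}"
            )
        out[trait] = (col == one_state).to_numpy(dtype=float)
        encoding[trait] = (trait,)

    shape = df["spine_shape"].astype(str)
    bad = ~shape.isin(SHAPE_STATES)
    if bad.any():
        raise TraitValidationError(
            f"spine_shape has states outside {SHAPE_STATES}: "
            f"{sorted(shape[bad].unique())}"
        )
    shape_cols = []
    for state in SHAPE_STATES:
        cname = f"spine_shape[{state}]"
        out[cname] = (shape == state).to_numpy(dtype=float)
        shape_cols.append(cname)
    encoding["spine_shape"] = tuple(shape_cols)

    ordered_cols: list[str] = []
    for var in VARIABLES:
        ordered_cols.extend(encoding[var])
    data = pd.DataFrame(out, index=df["species_id"].to_numpy())[ordered_cols]
    return TraitMatrix(data=data, encoding=encoding)


def cluster_syndromes(
    matrix: TraitMatrix, n_clusters: int = 4
) -> tuple[pd.Series, np.ndarray]:
    """Ward clustering of the encoded matrix.

    Returns ``(assignment, linkage_matrix)`` where ``assignment`` maps each
    species to a cluster label 1..n_clusters.  The partition is invariant to
    the ordering of the input species (labels follow scipy's convention).
    """
    n = len(matrix.data)
    if n_clusters > n:
        raise ValueError(f"n_clusters={n_clusters} exceeds n_species={n}")
    Z = linkage(matrix.values, method="ward")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return pd.Series(labels, index=matrix.data.index, name="cluster"), Z


def correlation_ratio(matrix: TraitMatrix, assignment: pd.Series) -> pd.Series:
    """Per-variable eta^2: between-cluster SS / total SS, in [0, 1].

    Variables encoded over several columns (the one-hot shape trait) report
    the mean of their columns' ratios.  A zero-variance column contributes 0.
    """
    groups = assignment.reindex(matrix.data.index).to_numpy()
    if pd.isna(groups).any():
        raise ValueError("assignment must cover every species in the matrix")
    X = matrix.values
    overall = X.mean(axis=0)
    total_ss = ((X - overall) ** 2).sum(axis=0)
    between_ss = np.zeros_like(total_ss)
    for g in np.unique(groups):
        sel = groups == g
        between_ss += sel.sum() * (X[sel].mean(axis=0) - overall) ** 2
    col_eta = np.where(total_ss > 0, between_ss / np.maximum(total_ss, 1e-300), 0.0)
    col_eta = pd.Series(col_eta, index=matrix.data.columns)
    order = [v for v in VARIABLES if v in matrix.encoding] + [
        v for v in matrix.encoding if v not in VARIABLES
    ]
    return pd.Series(
        {var: float(col_eta[list(matrix.encoding[var])].mean()) for var in order},
        name="eta_squared",
    )[order]


def ordination(matrix: TraitMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal-component decomposition of the centred trait matrix.

    Returns ``(coordinates, variance_pct)``: species coordinates on all
    non-degenerate axes and the percentage of variance carried by each axis
    (non-increasing; sums to 100 over the retained axes).
    """
    X = matrix.values
    if X.shape[0] < 3:
        raise ValueError("ordination needs at least 3 species")
    Xc = X - X.mean(axis=0)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    keep = S > 1e-12 * max(S[0], 1.0) if S.size else np.array([], bool)
    if not np.any(keep):
        raise ValueError("degenerate trait matrix: all species identical")
    U, S = U[:, keep], S[keep]
    coords = U * S
    var_pct = 100.0 * S**2 / np.sum(S**2)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=matrix.data.index, columns=cols), var_pct


def read_trait_table(path) -> pd.DataFrame:
    """Read a trait CSV (one row per species, TraitRecord field columns)."""
    df = pd.read_csv(path)
    required = {"species_id", *VARIABLES}
    missing = required - set(df.columns)
    if missing:
        raise TraitValidationError(f"trait table missing columns: {sorted(missing)}")
    return df
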