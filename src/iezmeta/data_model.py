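"""Pairwise abundance-comparison records and their validation.

The unit of analysis is a paired comparison between the mean abundance of a
species at a site near linear infrastructure (treatment) and at a paired
control site further away, together with the moderators used downstream:
distance to the infrastructure, infrastructure type, habitat class, and
species traits (body mass, percentage of carnivorous diet).

Records are held in a flat :class:`pandas.DataFrame` with one row per
comparison; the shared-control relationship between several distances of the
same species within a study is reconstructed from the equality of
``(study_id, species_id)`` and the control columns.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Closed vocabulary for taxonomic groups.
TAXON_GROUPS = ("mammal", "bird", "reptile", "amphibian")

#: Closed vocabulary for infrastructure classes. ``power_line`` is a distinct
#: level for birds only; for other taxa power lines are folded into
#: ``non_traffic``.
INFRA_TYPES = ("paved_road", "unpaved_road", "power_line", "non_traffic")

#: Closed vocabulary for habitat classes.
HABITATS = ("open", "closed")

#: Fixed CSV schema, one row per pairwise comparison.
COLUMNS = (
    "comparison_id", "source_id", "study_id", "species_id",
    "taxon_group", "clade", "distance_m", "infra_type", "habitat",
    "mean_treat", "sd_treat", "n_treat",
    "mean_ctrl", "sd_ctrl", "n_ctrl",
    "scale_D", "body_mass_g", "diet_pct", "quality_a", "quality_b",
)

_NUMERIC = (
    "distance_m", "mean_treat", "sd_treat", "n_treat",
    "mean_ctrl", "sd_ctrl", "n_ctrl", "scale_D",
    "body_mass_g", "diet_pct", "quality_a", "quality_b",
)


class SchemaError(ValueError):
    """The input file does not match the comparisons schema."""


class ClassificationError(ValueError):
    """A free-text infrastructure or habitat label could not be mapped."""


@dataclasses.dataclass(frozen=True)
class AbundanceComparison:
    """One paired disturbed/control abundance record."""

    comparison_id: str
    source_id: str
    study_id: str
    species_id: str
    taxon_group: str
    clade: str
    distance_m: float
    infra_type: str
    habitat: str
    mean_treat: float
    sd_treat: float | None
    n_treat: int
    mean_ctrl: float
    sd_ctrl: float | None
    n_ctrl: int
    scale_D: float
    body_mass_g: float
    diet_pct: float | None
    quality_a: int
    quality_b: int


def _row_problems(row: pd.Series) -> list[str]:
    problems = []
    if row["taxon_group"] not in TAXON_GROUPS:
        problems.append(f"unknown taxon_group {row['taxon_group']!r}")
    if row["infra_type"] not in INFRA_TYPES:
        problems.append(f"unknown infra_type {row['infra_type']!r}")
    elif row["infra_type"] == "power_line" and row["taxon_group"] != "bird":
        problems.append("power_line is a distinct level for birds only")
    if row["habitat"] not in HABITATS:
        problems.append(f"unknown habitat {row['habitat']!r}")
    if not np.isfinite(row["distance_m"]) or row["distance_m"] < 0:
        problems.append("distance_m must be >= 0")
    for col in ("mean_treat", "mean_ctrl"):
        if not np.isfinite(row[col]) or row[col] < 0:
            problems.append(f"{col} must be >= 0")
    for col in ("sd_treat", "sd_ctrl"):
        if not pd.isna(row[col]) and row[col] < 0:
            problems.append(f"{col} must be >= 0 or missing")
    for col in ("n_treat", "n_ctrl"):
        if not np.isfinite(row[col]) or row[col] < 1 or row[col] != int(row[col]):
            problems.append(f"{col} must be an integer >= 1")
    if not np.isfinite(row["scale_D"]) or row["scale_D"] <= 0:
        problems.append("scale_D must be > 0")
    if not np.isfinite(row["body_mass_g"]) or row["body_mass_g"] <= 0:
        problems.append("body_mass_g must be > 0")
    needs_diet = row["taxon_group"] in ("mammal", "bird")
    if needs_diet and pd.isna(row["diet_pct"]):
        problems.append("diet_pct required for mammals and birds")
    if not pd.isna(row["diet_pct"]) and not 0 <= row["diet_pct"] <= 100:
        problems.append("diet_pct must be in [0, 100]")
    for col in ("quality_a", "quality_b"):
        if row[col] not in (0, 1):
            problems.append(f"{col} must be 0 or 1")
    return problems


def validate_comparisons(
    df: pd.DataFrame, *, on_invalid: str = "reject"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Validate a comparisons table against the record invariants.

    Parameters
    ----------
    df
        Table with the :data:`COLUMNS` schema.
    on_invalid
        ``"reject"`` drops invalid rows, ``"raise"`` raises on the first.

    Returns
    -------
    valid, rejects
        The validated records and a table of rejected rows with a
        ``reject_reason`` column of row-level diagnostics.
    """
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = df.loc[:, list(COLUMNS)].copy()
    for col in _NUMERIC:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce")
            rows = df.index[bad.isna() & df[col].notna()].tolist()
            raise SchemaError(
                f"non-numeric value in column {col!r} at row(s) {rows}"
            ) from exc

    reasons = df.apply(_row_problems, axis=1)
    # one source per study
    study_sources = df.groupby("study_id")["source_id"].nunique()
    multi = set(study_sources.index[study_sources > 1])
    if multi:
        extra = df["study_id"].isin(multi)
        reasons = reasons.mask(
            extra, reasons[extra].apply(
                lambda r: r + ["study_id maps to more than one source_id"])
        )
    bad = reasons.str.len() > 0
    if bad.any() and on_invalid == "raise":
        i = df.index[bad][0]
        raise ValueError(f"invalid record at row {i}: {'; '.join(reasons[i])}")
    rejects = df.loc[bad].copy()
    rejects["reject_reason"] = reasons[bad].str.join("; ")
    return df.loc[~bad].reset_index(drop=True), rejects


def read_comparisons(
    path: str | Path, *, on_invalid: str = "reject"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a comparisons CSV.

    Missing SDs are empty cells and are kept as ``NaN`` (never coerced to
    zero). Returns ``(valid, rejects)`` as in :func:`validate_comparisons`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"comparisons file not found: {path}. The full field database is "
            "a separate archived deposit and is not bundled with this package."
        )
    df = pd.read_csv(path, dtype={c: str for c in (
        "comparison_id", "source_id", "study_id", "species_id",
        "taxon_group", "clade", "infra_type", "habitat")})
    return validate_comparisons(df, on_invalid=on_invalid)


def write_comparisons(df: pd.DataFrame, path: str | Path) -> None:
    """Write a comparisons table to CSV (missing values as empty cells)."""
    df.loc[:, list(COLUMNS)].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Free-text label classification

#: Default keyword mapping from free-text infrastructure labels to classes.
#: Power-line labels map to ``power_line`` here; :func:`classify_levels`
#: folds them into ``non_traffic`` for all taxa except birds.
DEFAULT_INFRA_MAP: Mapping[str, str] = {
    "highway": "paved_road",
    "motorway": "paved_road",
    "paved": "paved_road",
    "asphalt": "paved_road",
    "dirt": "unpaved_road",
    "gravel": "unpaved_road",
    "unpaved": "unpaved_road",
    "logging": "unpaved_road",
    "power": "power_line",
    "transmission": "power_line",
    "trail": "non_traffic",
    "seismic": "non_traffic",
    "pipeline": "non_traffic",
}

#: Default keyword mapping from free-text habitat labels to open/closed.
DEFAULT_HABITAT_MAP: Mapping[str, str] = {
    "grassland": "open",
    "cropland": "open",
    "shrubland": "open",
    "savanna": "open",
    "forest": "closed",
    "woodland": "closed",
}


def _match(label: str, table: Mapping[str, str]) -> str | None:
    norm = label.strip().lower()
    if norm in table:
        return table[norm]
    for key, value in table.items():
        if key in norm:
            return value
    return None


def classify_levels(
    raw_infra: str,
    raw_habitat: str,
    taxon_group: str,
    *,
    infra_map: Mapping[str, str] = DEFAULT_INFRA_MAP,
    habitat_map: Mapping[str, str] = DEFAULT_HABITAT_MAP,
) -> tuple[str, str]:
    """Map free-text labels onto the closed infrastructure/habitat vocabulary.

    Pure and deterministic. Power-line labels classify as ``power_line`` for
    birds and as ``non_traffic`` for mammals, reptiles and amphibians, where
    the extra collision risk that justifies a separate level does not apply.
    """
    infra = _match(raw_infra, infra_map)
    if infra is None:
        raise ClassificationError(f"unmapped infrastructure label: {raw_infra!r}")
    if infra == "power_line" and taxon_group != "bird":
        infra = "non_traffic"
    habitat = _match(raw_habitat, habitat_map)
    if habitat is None:
        raise ClassificationError(f"unmapped habitat label: {raw_habitat!r}")
    return infra, habitat


def aggregate_genus_traits(
    member_traits: Sequence[tuple[float, float]],
) -> tuple[float, float]:
    """Mean body mass and diet across the species of a genus aggregate."""
    if len(member_traits) == 0:
        raise ValueError("cannot aggregate traits over an empty member list")
    arr = np.asarray(member_traits, dtype=float)
    return float(arr[:, 0].mean()), float(arr[:, 1].mean())


def quality_subset(
    df: pd.DataFrame,
    *,
    drop_genus_aggregates: bool = False,
    drop_unverified_controls: bool = False,
) -> pd.DataFrame:
    """Filter records on the two binary quality criteria.

    ``quality_a = 0`` marks abundances aggregated over multiple species;
    ``quality_b = 0`` marks records whose control site was not explicitly
    undisturbed (or closer than the species' home range).
    """
    keep = pd.Series(True, index=df.index)
    if drop_genus_aggregates:
        keep &= df["quality_a"] == 1
    if drop_unverified_controls:
        keep &= df["quality_b"] == 1
    return df.loc[keep].reset_index(drop=True)
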