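"""Fixed-effect design matrices and random-effects groupings.

Distance enters the meta-regressions as log10 metres (clamped at 1 m so the
intercept is the prediction "at 1 m"), body mass as log10 grams, diet as a
raw percentage in [0, 100]. Habitat and infrastructure type are treatment-
coded with ``closed`` and ``non_traffic`` as reference levels; continuous
moderators are deliberately uncentered so that printed coefficient tables
can be used directly for prediction.

The random-effects structure has five variance components: observation-level
residual heterogeneity, clade (order for mammals/birds, family for reptiles/
amphibians), species nested in clade, data source (publication), and study
nested in source.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np
import pandas as pd

#: Recognised moderator terms, in canonical order.
TERMS = (
    "intercept", "distance", "distance2", "diet", "bm", "habitat",
    "infratype", "distance:diet", "distance2:diet", "distance:bm",
    "distance2:bm", "distance:habitat", "distance2:habitat",
)

#: Infrastructure dummy levels per taxon (reference level non_traffic).
_INFRA_LEVELS = {
    "bird": ("paved_road", "power_line", "unpaved_road"),
    "mammal": ("paved_road", "unpaved_road"),
    "reptile": ("paved_road", "unpaved_road"),
    "amphibian": ("paved_road", "unpaved_road"),
}

_DIET_TERMS = frozenset({"diet", "distance:diet", "distance2:diet"})


class SpecificationError(ValueError):
    """A moderator specification violates marginality or taxon rules."""


def _check_marginality(terms: Sequence[str]) -> None:
    ts = set(terms)
    unknown = ts - set(TERMS)
    if unknown:
        raise SpecificationError(f"unknown term(s): {sorted(unknown)}")
    if "intercept" not in ts:
        raise SpecificationError("models must include the intercept")
    if "distance2" in ts and "distance" not in ts:
        raise SpecificationError("distance2 requires distance")
    for z in ("diet", "bm", "habitat"):
        lin, quad = f"distance:{z}", f"distance2:{z}"
        if lin in ts and not {"distance", z} <= ts:
            raise SpecificationError(f"{lin} requires distance and {z}")
        if quad in ts:
            if lin not in ts:
                raise SpecificationError(f"{quad} requires {lin}")
            if "distance2" not in ts:
                raise SpecificationError(f"{quad} requires distance2")


@dataclasses.dataclass(frozen=True)
class ModeratorSpec:
    """An ordered set of fixed-effect terms satisfying marginality."""

    terms: tuple[str, ...]

    def __init__(self, terms: Sequence[str]):
        terms = tuple(terms)
        if "intercept" not in terms:
            terms = ("intercept",) + terms
        # canonical order
        terms = tuple(t for t in TERMS if t in terms)
        _check_marginality(terms)
        object.__setattr__(self, "terms", terms)

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def interactions_of(self, main: str) -> tuple[str, ...]:
        """Interaction terms in this spec that involve the given main effect.

        The distance main effect owns both ``distance:Z`` and
        ``distance2:Z`` interactions.
        """
        match = {main}
        if main == "distance":
            match.add("distance2")
        out = []
        for t in self.terms:
            if ":" in t and match & set(t.split(":")):
                out.append(t)
        return tuple(out)

    def drop(self, terms_to_drop: Sequence[str]) -> "ModeratorSpec":
        return ModeratorSpec([t for t in self.terms if t not in set(terms_to_drop)])


@dataclasses.dataclass(frozen=True)
class RandomEffectsSpec:
    """Ordered grouping factors, one variance component each."""

    components: tuple[str, ...] = (
        "observation", "clade", "species", "source", "study")

    def build_groups(self, df: pd.DataFrame) -> list[np.ndarray]:
        """Integer group labels per component, aligned to the rows of df."""
        n = len(df)
        keys = {
            "observation": np.arange(n),
            "clade": pd.factorize(df["clade"])[0],
            "species": pd.factorize(
                df["clade"].astype(str) + "/" + df["species_id"].astype(str))[0],
            "source": pd.factorize(df["source_id"])[0],
            "study": pd.factorize(
                df["source_id"].astype(str) + "/" + df["study_id"].astype(str))[0],
        }
        return [np.asarray(keys[c]) for c in self.components]


def transform_distance(d_m):
    """log10 distance with sub-metre records clamped to 1 m (x = 0)."""
    d = np.asarray(d_m, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    out = np.log10(np.maximum(d, 1.0))
    return out.item() if out.ndim == 0 else out


def _base_columns(df: pd.DataFrame, taxon_group: str) -> dict[str, np.ndarray]:
    n = len(df)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(n)}
    x = transform_distance(df["distance_m"].to_numpy())
    cols["distance"] = x
    cols["distance2"] = x**2
    if "diet_pct" in df.columns:
        cols["diet"] = df["diet_pct"].to_numpy(dtype=float)
    cols["bm"] = np.log10(df["body_mass_g"].to_numpy(dtype=float))
    cols["habitat"] = (df["habitat"] == "open").to_numpy(dtype=float)
    return cols


def build_design(
    df: pd.DataFrame, spec: ModeratorSpec, taxon_group: str
) -> tuple[np.ndarray, list[str]]:
    """Design matrix and column labels for a moderator specification.

    Column order follows the spec's (canonical) term order; the infratype
    term expands into one dummy per non-reference level of the taxon's
    vocabulary. Requesting diet terms for reptiles or amphibians is an
    error (diet data exist for mammals and birds only).
    """
    if taxon_group in ("reptile", "amphibian") and _DIET_TERMS & set(spec.terms):
        raise SpecificationError(
            f"diet terms are not available for taxon {taxon_group!r}")
    base = _base_columns(df, taxon_group)
    columns: list[np.ndarray] = []
    labels: list[str] = []
    for term in spec.terms:
        if term == "infratype":
            for level in _INFRA_LEVELS[taxon_group]:
                columns.append((df["infra_type"] == level).to_numpy(dtype=float))
                labels.append(f"infratype[{level}]")
        elif ":" in term:
            a, b = term.split(":")
            columns.append(base[a] * base[b])
            labels.append(term)
        else:
            columns.append(base[term])
            labels.append(term)
    X = np.column_stack(columns) if columns else np.empty((len(df), 0))
    return X, labels


#: Default per-taxon term menus for candidate enumeration. Trait moderators
#: (diet, body mass) and their distance interactions apply to mammals and
#: birds; all taxa get distance, habitat and infrastructure-type terms.
DEFAULT_MENUS = {
    "mammal": ("distance", "distance2", "diet", "bm", "habitat", "infratype",
               "distance:diet", "distance2:diet", "distance:bm",
               "distance2:bm", "distance:habitat", "distance2:habitat"),
    "bird": ("distance", "distance2", "diet", "bm", "habitat", "infratype",
             "distance:diet", "distance2:diet", "distance:bm",
             "distance2:bm", "distance:habitat", "distance2:habitat"),
    "reptile": ("distance", "distance2", "habitat", "infratype",
                "distance:habitat", "distance2:habitat"),
    "amphibian": ("distance", "distance2", "habitat", "infratype",
                  "distance:habitat", "distance2:habitat"),
}


def enumerate_candidate_specs(
    taxon_group: str, menu: Sequence[str] | None = None
) -> list[ModeratorSpec]:
    """All marginality-respecting subsets of a term menu (plus intercept).

    Always includes the intercept-only model. The default menu per taxon is
    :data:`DEFAULT_MENUS`; pass ``menu`` to restrict (e.g. distance terms
    only).
    """
    if menu is None:
        menu = DEFAULT_MENUS[taxon_group]
    menu = tuple(menu)
    specs = []
    for r in range(len(menu) + 1):
        for subset in itertools.combinations(menu, r):
            try:
                specs.append(ModeratorSpec(subset))
            except SpecificationError:
                continue
    return specs
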