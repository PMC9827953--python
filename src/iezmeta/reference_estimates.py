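"""Published fixed-effect estimates for the four vertebrate classes.

These are the coefficient tables of the AICc-selected meta-regressions
from a published global synthesis of linear-infrastructure impacts on
vertebrate abundance (853-2462 residual df per taxon, distances 0-4.5 km),
bundled as inputs so that predictions and infrastructure-effect zones can
be computed without refitting. Coefficients are on the package's design
coding: distance as log10 metres clamped at 1 m, body mass as log10 grams,
diet as a raw percentage, habitat reference level ``closed``,
infrastructure reference level ``non_traffic``. Estimates are printed to
two decimals, so derived quantities carry rounding error of that order.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .meta_design import ModeratorSpec, build_design

#: Term lists and estimates of the selected model per taxon; coefficient
#: order follows the canonical term order of :mod:`iezmeta.meta_design`
#: (infratype expands to paved_road, power_line, unpaved_road dummies for
#: birds).
REFERENCE_COEFFICIENTS: dict[str, dict] = {
    "mammal": {
        "terms": ("distance", "distance2", "diet", "bm", "habitat",
                  "distance:diet", "distance:bm", "distance2:bm",
                  "distance:habitat"),
        "beta": (-0.00, 0.45, -0.16, 0.02, -0.08, 0.29,
                 -0.01, -0.20, 0.09, -0.23),
    },
    "bird": {
        "terms": ("distance", "diet", "habitat", "infratype",
                  "distance:diet", "distance:habitat"),
        "beta": (0.05, -0.04, -0.01, -0.47, -0.45, -0.29, -0.32,
                 0.01, 0.34),
    },
    "reptile": {
        "terms": ("distance", "distance2", "habitat", "distance:habitat"),
        "beta": (0.18, -0.44, 0.15, -0.67, 0.38),
    },
    "amphibian": {
        "terms": ("distance", "distance2"),
        "beta": (-0.74, 0.91, -0.32),
    },
}


@dataclasses.dataclass(frozen=True)
class ReferenceModel:
    """A coefficient-only model usable for prediction and IEZ derivation."""

    taxon_group: str
    spec: ModeratorSpec
    beta: np.ndarray
    beta_labels: tuple[str, ...]
    beta_cov: None = None
    data: None = None


def reference_model(taxon_group: str) -> ReferenceModel:
    """Build the bundled published model for one taxon."""
    try:
        entry = REFERENCE_COEFFICIENTS[taxon_group]
    except KeyError:
        raise ValueError(f"no reference model for taxon {taxon_group!r}")
    spec = ModeratorSpec(entry["terms"])
    # derive labels from a probe design row so dummy expansion matches
    probe = pd.DataFrame({
        "distance_m": [1.0], "diet_pct": [0.0], "body_mass_g": [100.0],
        "habitat": ["closed"], "infra_type": ["non_traffic"]})
    _, labels = build_design(probe, spec, taxon_group)
    beta = np.asarray(entry["beta"], dtype=float)
    if len(beta) != len(labels):
        raise RuntimeError("coefficient count does not match design labels")
    return ReferenceModel(taxon_group=taxon_group, spec=spec, beta=beta,
                          beta_labels=tuple(labels))
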