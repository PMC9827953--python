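"""Distance-response predictions and infrastructure-effect zones.

For a fitted meta-regression, the predicted log response ratio at a given
distance is quadratic in x = log10(distance). The infrastructure-effect
zone (IEZ) is the smallest distance at which that prediction crosses zero,
i.e. where the modelled abundance returns to its control level; its
confidence bounds are the first zero-crossings of the pointwise 95%
confidence envelope. Curves that never move back to zero within the search
range yield an undefined IEZ (e.g. a response that keeps declining with
distance).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.optimize

from .data_model import HABITATS, INFRA_TYPES
from .meta_design import build_design

#: Default search ceiling for zero crossings, metres; far beyond the
#: largest observed distance in infrastructure field studies (~4.5 km).
D_MAX_DEFAULT = 100_000.0


@dataclasses.dataclass
class PredictionResult:
    lrr: float
    se: float
    ci_low: float
    ci_high: float
    extrapolated: bool = False


@dataclasses.dataclass
class IEZEstimate:
    """Zero-crossing distance of a modelled distance-response curve."""

    iez_m: float | None
    ci_low_m: float | None          # None = no lower envelope crossing
    ci_high_m: float | None         # None = unbounded within the range
    sign_near: str                  # effect direction at 1 m: "+" or "-"
    defined: bool


def _moderator_frame(distance_m, diet_pct, body_mass_g, habitat, infra_type):
    if habitat not in HABITATS:
        raise ValueError(f"unknown habitat level: {habitat!r}")
    if infra_type not in INFRA_TYPES:
        raise ValueError(f"unknown infrastructure level: {infra_type!r}")
    return pd.DataFrame({
        "distance_m": [float(distance_m)],
        "diet_pct": [0.0 if diet_pct is None else float(diet_pct)],
        "body_mass_g": [100.0 if body_mass_g is None else float(body_mass_g)],
        "habitat": [habitat],
        "infra_type": [infra_type],
    })


def _design_row(model, distance_m, diet_pct, body_mass_g, habitat, infra_type):
    frame = _moderator_frame(distance_m, diet_pct, body_mass_g,
                             habitat, infra_type)
    X, labels = build_design(frame, model.spec, model.taxon_group)
    if labels != list(model.beta_labels):
        raise ValueError("design labels do not match the fitted coefficients")
    return X[0]


def predict_lrr(
    model,
    distance_m: float,
    *,
    diet_pct: float | None = None,
    body_mass_g: float | None = None,
    habitat: str = "closed",
    infra_type: str = "non_traffic",
) -> PredictionResult:
    """Model prediction (with 95% CI) at given moderator values.

    ``model`` may be any object exposing ``spec``, ``taxon_group``,
    ``beta``, ``beta_labels`` and optionally ``beta_cov`` and fitted
    ``data`` (used to flag extrapolation beyond the fitted distance range).
    """
    row = _design_row(model, distance_m, diet_pct, body_mass_g,
                      habitat, infra_type)
    lrr = float(row @ model.beta)
    cov = getattr(model, "beta_cov", None)
    se = float(np.sqrt(row @ cov @ row)) if cov is not None else float("nan")
    z = 1.959963984540054
    extrapolated = False
    data = getattr(model, "data", None)
    if data is not None and "distance_m" in data:
        extrapolated = not (data["distance_m"].min() <= distance_m
                            <= data["distance_m"].max())
    return PredictionResult(lrr=lrr, se=se, ci_low=lrr - z * se,
                            ci_high=lrr + z * se, extrapolated=extrapolated)


def _curve_coefficients(model, moderators) -> tuple[float, float, float]:
    """Exact (c0, c1, c2) of the quadratic prediction in x = log10(d)."""
    preds = [float(_design_row(model, 10.0**x, *moderators) @ model.beta)
             for x in (0.0, 1.0, 2.0)]
    c0 = preds[0]
    c2 = (preds[2] - 2 * preds[1] + preds[0]) / 2.0
    c1 = preds[1] - preds[0] - c2
    return c0, c1, c2


def _crossing_roots(c0: float, c1: float, c2: float,
                    xmax: float) -> list[float]:
    """Sign-changing roots of c2 x^2 + c1 x + c0 within (0, xmax]."""
    if abs(c2) < 1e-14:
        if abs(c1) < 1e-14:
            return []
        roots = [-c0 / c1]
    else:
        disc = c1 * c1 - 4 * c2 * c0
        if disc < 0:
            return []
        if disc == 0:
            return []                       # tangency: no sign change
        sq = np.sqrt(disc)
        roots = sorted([(-c1 - sq) / (2 * c2), (-c1 + sq) / (2 * c2)])
    return [r for r in roots if 0 < r <= xmax]


def _first_envelope_crossing(model, moderators, offset_sign: float,
                             target_sign: float, xmax: float) -> float | None:
    """Smallest x where f(x) + offset_sign*1.96*se(x) leaves target_sign.

    Returns 0.0 when the envelope is already across zero at x = 0, None
    when it never crosses within [0, xmax].
    """
    z = 1.959963984540054

    def env(x):
        p = predict_lrr(model, 10.0**x, diet_pct=moderators[0],
                        body_mass_g=moderators[1], habitat=moderators[2],
                        infra_type=moderators[3])
        return p.lrr + offset_sign * z * p.se

    xs = np.linspace(0.0, xmax, 512)
    vals = np.array([env(x) for x in xs])
    onside = np.sign(vals) == target_sign
    if not onside[0]:
        return 0.0
    cross = np.flatnonzero(onside[:-1] & ~onside[1:])
    if len(cross) == 0:
        return None
    i = cross[0]
    if vals[i + 1] == 0.0:
        return float(xs[i + 1])
    return float(scipy.optimize.brentq(env, xs[i], xs[i + 1], xtol=1e-10))


def find_iez(
    model,
    *,
    diet_pct: float | None = None,
    body_mass_g: float | None = None,
    habitat: str = "closed",
    infra_type: str = "non_traffic",
    d_max: float = D_MAX_DEFAULT,
) -> IEZEstimate:
    """Smallest distance in [1 m, d_max] where the prediction crosses zero.

    Closed-form roots of the quadratic in log10 distance are used. The IEZ
    is undefined when the curve never crosses zero within range (a response
    that does not move back toward the control level with distance).
    Confidence bounds are the first crossings of the pointwise 95%
    envelope; a bound is ``None`` (unbounded) when that envelope never
    crosses within range, and 0 m when it is already across at 1 m.
    """
    if d_max < 1:
        raise ValueError("d_max must be at least 1 m")
    moderators = (diet_pct, body_mass_g, habitat, infra_type)
    xmax = float(np.log10(d_max))
    c0, c1, c2 = _curve_coefficients(model, moderators)

    if c0 == 0.0:
        slope = c1
        sign_near = "+" if slope > 0 else "-"
        return IEZEstimate(iez_m=1.0, ci_low_m=None, ci_high_m=None,
                           sign_near=sign_near, defined=True)
    sign_near = "+" if c0 > 0 else "-"
    roots = _crossing_roots(c0, c1, c2, xmax)
    if not roots:
        return IEZEstimate(iez_m=None, ci_low_m=None, ci_high_m=None,
                           sign_near=sign_near, defined=False)
    x_star = roots[0]
    iez_m = float(10.0**x_star)

    ci_low_m = ci_high_m = None
    cov = getattr(model, "beta_cov", None)
    if cov is not None:
        target = 1.0 if sign_near == "+" else -1.0
        # the envelope on the zero side of the curve crosses first
        first = _first_envelope_crossing(model, moderators, -target, target,
                                         xmax)
        last = _first_envelope_crossing(model, moderators, target, target,
                                        xmax)
        ci_low_m = None if first is None else float(10.0**first) if first > 0 else 0.0
        ci_high_m = None if last is None else float(10.0**last) if last > 0 else 0.0
    return IEZEstimate(iez_m=iez_m, ci_low_m=ci_low_m, ci_high_m=ci_high_m,
                       sign_near=sign_near, defined=True)


def iez_table(
    model,
    *,
    bm_values: dict[str, float] | None = None,
    diet_levels: Sequence[float] = (0.0, 80.0),
    habitats: Sequence[str] = ("open", "closed"),
    d_max: float = D_MAX_DEFAULT,
) -> pd.DataFrame:
    """Grid of IEZ estimates over trait classes and habitats.

    Body-mass classes default to the 10th percentile (small), median
    (medium) and 90th percentile (large) of the fitted data when available.
    Trait dimensions absent from the model collapse to a single cell.
    Models with an infrastructure-type term are evaluated at paved roads
    (the dominant class in the field data); others at the reference level.
    """
    has_bm = any(t in model.spec.terms for t in ("bm",))
    has_diet = any("diet" in t for t in model.spec.terms)
    has_infra = "infratype" in model.spec.terms
    infra = "paved_road" if has_infra else "non_traffic"

    if has_bm and bm_values is None:
        data = getattr(model, "data", None)
        if data is None or "body_mass_g" not in data:
            raise ValueError("bm_values required for models without data")
        q = data["body_mass_g"].quantile([0.10, 0.50, 0.90])
        bm_values = {"small": float(q.iloc[0]), "medium": float(q.iloc[1]),
                     "large": float(q.iloc[2])}
    bm_grid = bm_values if has_bm else {"-": None}
    diet_grid = tuple(diet_levels) if has_diet else ("-",)

    rows = []
    for diet in diet_grid:
        for bm_label, bm in bm_grid.items():
            for habitat in habitats:
                est = find_iez(
                    model,
                    diet_pct=None if diet == "-" else float(diet),
                    body_mass_g=bm, habitat=habitat, infra_type=infra,
                    d_max=d_max)
                rows.append({
                    "taxon": model.taxon_group,
                    "diet_class": diet if diet == "-" else
                    ("carnivore" if diet >= 80 else "non-carnivore"),
                    "body_mass": bm_label,
                    "body_mass_g": bm,
                    "habitat": habitat,
                    "iez_m": est.iez_m,
                    "ci_low_m": est.ci_low_m,
                    "ci_high_m": est.ci_high_m,
                    "sign_near": est.sign_near,
                    "defined": est.defined,
                })
    return pd.DataFrame(rows)
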