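"""AICc ranking of candidate moderator specifications.

Every candidate is fitted to the same effect-size set with the same
random-effects structure; candidates are ranked by small-sample AIC
computed from the full likelihood at the (REML by default) estimates, and
the minimum-AICc specification is selected, breaking near-ties toward the
model with fewer parameters.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import pandas as pd

from .meta_design import ModeratorSpec, RandomEffectsSpec
from .meta_engine import FittedMetaModel, aicc, fit_model

logger = logging.getLogger(__name__)

#: AICc differences below this are treated as ties (fewer parameters wins).
_TIE_TOL = 1e-6


@dataclasses.dataclass
class SelectionResult:
    """Ranked candidate table plus the selected specification."""

    table: pd.DataFrame               # spec, k, loglik_full, aicc, delta_aicc
    best_spec: ModeratorSpec
    best_model: FittedMetaModel


def select_model(
    effect_set,
    candidates: Sequence[ModeratorSpec],
    re_spec: RandomEffectsSpec,
    taxon_group: str,
    *,
    multistart: bool = True,
) -> SelectionResult:
    """Fit all candidate specifications and select the minimum-AICc model.

    Non-converged or inestimable candidates are excluded with a logged
    warning; an error is raised only if every candidate fails.
    """
    if not candidates:
        raise ValueError("need at least one candidate specification")
    rows = []
    models: dict[int, FittedMetaModel] = {}
    for i, spec in enumerate(candidates):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = fit_model(effect_set, spec, re_spec, taxon_group,
                                  multistart=multistart, with_stats=False)
            if not model.converged:
                logger.warning("candidate %s did not converge; excluded",
                               "+".join(spec.terms))
                continue
            crit = aicc(model)
        except (ValueError, FloatingPointError) as exc:
            logger.warning("candidate %s failed: %s; excluded",
                           "+".join(spec.terms), exc)
            continue
        models[i] = model
        rows.append({"candidate": i, "spec": "+".join(spec.terms),
                     "k": model.n_params,
                     "loglik_full": model.loglik_full, "aicc": crit})
    if not rows:
        raise RuntimeError("all candidate models failed to fit")
    table = pd.DataFrame(rows).sort_values(
        ["aicc", "k"], kind="stable").reset_index(drop=True)
    # near-ties toward fewer parameters
    best_aicc = table["aicc"].iloc[0]
    tied = table[table["aicc"] <= best_aicc + _TIE_TOL]
    best_row = tied.sort_values(["k", "aicc"], kind="stable").iloc[0]
    table["delta_aicc"] = table["aicc"] - table["aicc"].iloc[0]
    best_idx = int(best_row["candidate"])
    best_model = models[best_idx]
    # attach the full fit statistics to the winner only
    from .meta_engine import q_e, q_m, r2_nakagawa
    best_model.qe = q_e(best_model.y, best_model.V, best_model.X)
    nonint = [t for t in best_model.spec.terms if t != "intercept"]
    if nonint:
        best_model.qm = q_m(best_model, nonint, drop_interactions=False)
    best_model.r2_marginal, best_model.r2_conditional = r2_nakagawa(best_model)
    return SelectionResult(table=table, best_spec=candidates[best_idx],
                           best_model=best_model)
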