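"""Delta-corrected log response ratios and their sampling (co)variances.

The effect size is the natural log of the ratio of mean abundance at the
disturbed site to mean abundance at the paired control site, with a
second-order small-sample bias correction (the delta method applied to the
log of a ratio of sample means):

    LRR_delta = log(At/Ac) + 1/2 [ SDt^2/(nt At^2) - SDc^2/(nc Ac^2) ]

with sampling variance

    var = SDt^2/(nt At^2) + SDc^2/(nc Ac^2)
        + 1/2 [ SDt^4/(nt^2 At^4) + SDc^4/(nc^2 Ac^4) ].

Zero sample means (a species undetected at a site) are replaced by the
truncated mean 1/(2 n D), where D is the reporting-scale constant (e.g. the
number of trap nights behind a per-trap-night rate), so that the ratio is
defined. Effect sizes that divide different treatment distances by the same
control mean are sampling-correlated; the shared-control covariance is the
control's first-order variance contribution SDc^2/(nc Ac^2).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd


def truncated_mean(mean, n, D):
    """Truncated sample mean: the observed mean if positive, else 1/(2 n D)."""
    mean = np.asarray(mean, dtype=float)
    n = np.asarray(n)
    D = np.asarray(D, dtype=float)
    if np.any(n < 1) or np.any(D <= 0):
        raise ValueError("require n >= 1 and D > 0")
    out = np.where(mean > 0, mean, 1.0 / (2.0 * n * D))
    return out.item() if out.ndim == 0 else out


def lrr_delta(treat, ctrl):
    """Small-sample-corrected log response ratio.

    Parameters are ``(A, sd, n)`` triples for the treatment and control
    sides, where ``A`` is the (truncated) mean. Zero means must be replaced
    by :func:`truncated_mean` first.
    """
    at, sdt, nt = (np.asarray(v, dtype=float) for v in treat)
    ac, sdc, nc = (np.asarray(v, dtype=float) for v in ctrl)
    if np.any(at <= 0) or np.any(ac <= 0):
        raise ValueError("means must be > 0; apply truncated_mean first")
    out = np.log(at / ac) + 0.5 * (
        sdt**2 / (nt * at**2) - sdc**2 / (nc * ac**2)
    )
    return out.item() if out.ndim == 0 else out


def var_lrr_delta(treat, ctrl):
    """Delta-method sampling variance of the corrected log response ratio."""
    at, sdt, nt = (np.asarray(v, dtype=float) for v in treat)
    ac, sdc, nc = (np.asarray(v, dtype=float) for v in ctrl)
    if np.any(at <= 0) or np.any(ac <= 0):
        raise ValueError("means must be > 0; apply truncated_mean first")
    out = (
        sdt**2 / (nt * at**2)
        + sdc**2 / (nc * ac**2)
        + 0.5 * (sdt**4 / (nt**2 * at**4) + sdc**4 / (nc**2 * ac**4))
    )
    return out.item() if out.ndim == 0 else out


def geary_pass(A, sd, n):
    """Normality screen for ratio effect sizes (Geary's rule).

    True iff ``(A/sd) * 4 n^{3/2} / (1 + 4 n) >= 3``; ratio effect sizes
    whose standardized mean falls below 3 on either side are unreliable
    because the denominator mean is too close to zero.
    """
    A = np.asarray(A, dtype=float)
    sd = np.asarray(sd, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(sd <= 0):
        raise ValueError("geary_pass requires sd > 0")
    out = (A / sd) * (4.0 * n**1.5) / (1.0 + 4.0 * n) >= 3.0
    return bool(out) if out.ndim == 0 else out


def percentage_change(lrr):
    """Percentage abundance change implied by a log response ratio."""
    out = (np.exp(np.asarray(lrr, dtype=float)) - 1.0) * 100.0
    return out.item() if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# SD imputation

_SIDES = (("mean_treat", "sd_treat", "n_treat"),
          ("mean_ctrl", "sd_ctrl", "n_ctrl"))


def _truncated_cols(df: pd.DataFrame) -> pd.DataFrame:
    """Return df with helper columns a_treat/a_ctrl (truncated means)."""
    out = df.copy()
    out["a_treat"] = truncated_mean(
        df["mean_treat"].to_numpy(), df["n_treat"].to_numpy(),
        df["scale_D"].to_numpy())
    out["a_ctrl"] = truncated_mean(
        df["mean_ctrl"].to_numpy(), df["n_ctrl"].to_numpy(),
        df["scale_D"].to_numpy())
    return out


def impute_sd(
    df: pd.DataFrame,
    method: str = "poisson",
    *,
    seed: int | None = None,
    n_imputations: int = 100,
    k_neighbors: int = 5,
) -> pd.DataFrame | list[pd.DataFrame]:
    """Fill missing (or reported-zero) SDs.

    Methods
    -------
    poisson
        ``SD = sqrt(A_tilde)``: abundance counts are assumed Poisson so the
        variance equals the (truncated) mean. Deterministic; the default.
    bracken1992
        ``SD_i = A_i * (sum SD / sum A)`` over complete cases, i.e. the
        pooled SD-to-mean ratio of studies with complete information.
    hotdeck_nn
        Each missing SD is drawn uniformly from the ``k_neighbors`` complete
        cases nearest in ``|A_tilde|`` difference within the same
        taxon_group; repeated ``n_imputations`` times, returning a list of
        completed tables. Seed-reproducible.

    A reported SD of exactly zero is treated as missing. Flag columns
    ``sd_imputed_treat`` / ``sd_imputed_ctrl`` mark the filled cells.
    """
    work = _truncated_cols(df)
    for side, (_, sd_col, _) in zip(("treat", "ctrl"), _SIDES):
        miss = work[sd_col].isna() | (work[sd_col] == 0)
        work[f"sd_imputed_{side}"] = miss

    if method == "poisson":
        out = work.copy()
        for side, (_, sd_col, _) in zip(("treat", "ctrl"), _SIDES):
            miss = out[f"sd_imputed_{side}"]
            out.loc[miss, sd_col] = np.sqrt(out.loc[miss, f"a_{side}"])
        return out.drop(columns=["a_treat", "a_ctrl"])

    # donor-based methods: a "case" is one (mean, sd) cell
    cases = []
    for side, (_, sd_col, _) in zip(("treat", "ctrl"), _SIDES):
        sub = work.loc[~work[f"sd_imputed_{side}"],
                       [f"a_{side}", sd_col, "taxon_group"]]
        sub.columns = ["a", "sd", "taxon_group"]
        cases.append(sub)
    complete = pd.concat(cases, ignore_index=True)
    if complete.empty:
        raise ValueError(f"method {method!r} needs at least one complete case")

    if method == "bracken1992":
        ratio = complete["sd"].sum() / complete["a"].sum()
        out = work.copy()
        for side, (_, sd_col, _) in zip(("treat", "ctrl"), _SIDES):
            miss = out[f"sd_imputed_{side}"]
            out.loc[miss, sd_col] = out.loc[miss, f"a_{side}"] * ratio
        return out.drop(columns=["a_treat", "a_ctrl"])

    if method == "hotdeck_nn":
        rng = np.random.default_rng(seed)
        completed = []
        # donor indices per missing cell, computed once (deterministic)
        donor_sets: list[tuple[str, int, np.ndarray]] = []
        for side, (_, sd_col, _) in zip(("treat", "ctrl"), _SIDES):
            for i in work.index[work[f"sd_imputed_{side}"]]:
                pool = complete[complete["taxon_group"]
                                == work.at[i, "taxon_group"]]
                if pool.empty:
                    pool = complete
                dist = (pool["a"] - work.at[i, f"a_{side}"]).abs()
                # stable sort keeps record order on ties
                nearest = dist.sort_values(kind="stable").index[:k_neighbors]
                donor_sets.append((sd_col, i, pool.loc[nearest, "sd"].to_numpy()))
        for _ in range(n_imputations):
            out = work.copy()
            for sd_col, i, donors in donor_sets:
                out.at[i, sd_col] = rng.choice(donors)
            completed.append(out.drop(columns=["a_treat", "a_ctrl"]))
        return completed

    raise ValueError(f"unknown imputation method: {method!r}")


# ---------------------------------------------------------------------------
# Effect-size set assembly

@dataclasses.dataclass
class EffectSizeSet:
    """Ordered effect sizes with their full sampling variance-covariance.

    ``table`` has one row per effect size (value, variance, flags, and all
    moderators carried over from the comparisons table); ``vcov`` is the
    aligned square matrix whose diagonal equals the variances and whose
    off-diagonal entries are the shared-control covariances.
    """

    table: pd.DataFrame
    vcov: np.ndarray

    def __post_init__(self) -> None:
        v = self.vcov
        n = len(self.table)
        if v.shape != (n, n):
            raise ValueError("vcov shape does not match effect-size count")
        if not np.allclose(v, v.T):
            raise ValueError("vcov must be symmetric")
        if not np.allclose(np.diag(v), self.table["variance"].to_numpy()):
            raise ValueError("vcov diagonal must equal the variances")
        if np.linalg.eigvalsh(v).min() < -1e-10:
            raise ValueError("vcov must be positive semidefinite")

    @property
    def y(self) -> np.ndarray:
        return self.table["value"].to_numpy()

    def to_csv(self, table_path, vcov_path) -> None:
        """Serialize as an effect-size table plus a dense vcov CSV, both
        index-aligned by comparison_id."""
        self.table.to_csv(table_path, index=False)
        ids = self.table["comparison_id"]
        pd.DataFrame(self.vcov, index=ids, columns=ids).to_csv(vcov_path)


_CARRY = ("comparison_id", "source_id", "study_id", "species_id",
          "taxon_group", "clade", "distance_m", "infra_type", "habitat",
          "body_mass_g", "diet_pct", "quality_a", "quality_b")


def build_effect_size_set(df: pd.DataFrame) -> EffectSizeSet:
    """Compute effect sizes and assemble the shared-control vcov matrix.

    SDs must be complete (run :func:`impute_sd` first). Pairs of effect
    sizes within the same ``(study_id, species_id)`` that share identical
    control columns get covariance ``SDc^2 / (nc * Ac^2)``; all other pairs
    are independent.
    """
    if df["sd_treat"].isna().any() or df["sd_ctrl"].isna().any():
        raise ValueError("SDs must be complete; run impute_sd first")
    work = _truncated_cols(df.reset_index(drop=True))
    treat = (work["a_treat"].to_numpy(), work["sd_treat"].to_numpy(),
             work["n_treat"].to_numpy())
    ctrl = (work["a_ctrl"].to_numpy(), work["sd_ctrl"].to_numpy(),
            work["n_ctrl"].to_numpy())
    value = lrr_delta(treat, ctrl)
    variance = var_lrr_delta(treat, ctrl)

    table = work.loc[:, [c for c in _CARRY if c in work.columns]].copy()
    table["value"] = value
    table["variance"] = variance
    table["used_truncation_treat"] = work["mean_treat"] == 0
    table["used_truncation_ctrl"] = work["mean_ctrl"] == 0
    for side in ("treat", "ctrl"):
        col = f"sd_imputed_{side}"
        table[col] = work[col] if col in work.columns else False

    n = len(work)
    vcov = np.diag(variance.astype(float)) if n else np.zeros((0, 0))
    ctrl_var = ctrl[1] ** 2 / (ctrl[2] * ctrl[0] ** 2)
    groups = work.groupby(
        ["study_id", "species_id", "mean_ctrl", "sd_ctrl", "n_ctrl"],
        sort=False).indices
    for idx in groups.values():
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                i, j = idx[a], idx[b]
                vcov[i, j] = vcov[j, i] = ctrl_var[i]
    return EffectSizeSet(table=table, vcov=vcov)


def geary_subset(df: pd.DataFrame) -> pd.DataFrame:
    """Records whose treatment *and* control sides pass Geary's rule.

    Uses the (possibly imputed) SDs and truncated means; rows with zero SD
    on either side are excluded (the rule is undefined there).
    """
    work = _truncated_cols(df)
    ok = pd.Series(True, index=work.index)
    for side, (_, sd_col, n_col) in zip(("treat", "ctrl"), _SIDES):
        sd = work[sd_col]
        defined = sd.notna() & (sd > 0)
        passed = pd.Series(False, index=work.index)
        passed[defined] = geary_pass(
            work.loc[defined, f"a_{side}"].to_numpy(),
            sd[defined].to_numpy(),
            work.loc[defined, n_col].to_numpy())
        ok &= passed
    return df.loc[ok].reset_index(drop=True)
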