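"""Hierarchical infrastructure-abundance simulator with known truth.

Generates datasets with the structure of the field database behind the
meta-analysis: publications (sources) containing studies, studies sampling
several species at several distances from one piece of linear
infrastructure, with the farthest site of each study serving as the shared
control for all nearer (treatment) distances of the same species. Each
record's true log response ratio is a fixed-effects design row times the
true coefficients plus Gaussian random effects for clade, species, source,
study and observation. Observed site means are normal around the truth,
censored at zero (reproducing the real database's substantial fraction of
zero means), and site SDs are withheld at a configurable rate to exercise
the imputation step.

Amounts and rates default to the scale of the published database per
taxon: 863/2471/362/216 comparisons for mammals/birds/reptiles/amphibians,
zero-mean fractions of 20/19/20/26% and missing-SD fractions of
22/63/26/54%.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from . import data_model
from .meta_design import ModeratorSpec, build_design
from .reference_estimates import REFERENCE_COEFFICIENTS

#: Published database scale per taxon: number of comparisons, zero-mean
#: fraction, missing-SD fraction, and non-carnivore share of species.
_TAXON_SCALE = {
    "mammal": (863, 0.20, 0.22, 0.63),
    "bird": (2471, 0.19, 0.63, 0.73),
    "reptile": (362, 0.20, 0.26, None),
    "amphibian": (216, 0.26, 0.54, None),
}

#: log10 body-mass distributions (mean, sd) roughly matching the published
#: per-taxon ranges.
_BM_DIST = {"mammal": (2.5, 1.2), "bird": (1.8, 0.8),
            "reptile": (1.5, 1.0), "amphibian": (0.5, 0.8)}


@dataclasses.dataclass
class SimulationConfig:
    """Generator truth and structure for one taxon's dataset."""

    seed: int = 0
    taxon_group: str = "mammal"
    n_sources: int = 25
    studies_per_source: tuple[int, int] = (1, 3)
    species_per_study: tuple[int, int] = (1, 6)
    n_clades: int = 12
    distances_per_study: tuple[int, int] = (2, 5)   # incl. the far control
    max_distance_m: float = 4500.0
    true_terms: tuple[str, ...] | None = None       # default: published model
    true_beta: tuple[float, ...] | None = None
    true_sigma2: tuple[float, float, float, float, float] = (
        0.30, 0.05, 0.25, 0.10, 0.10)
    control_mean_scale: tuple[float, float] = (1.5, 1.0)  # lognormal mu, sd
    within_site_n: tuple[int, int] = (2, 6)
    sd_missing_rate: float | None = None            # default: taxon preset
    zero_rate_target: float | None = None           # default: taxon preset
    open_habitat_share: float = 0.31
    site_cv: float | None = None        # overrides the zero-rate calibration
    within_site_noise: bool = True
    count_mode: bool = False
    nb_dispersion: float = 2.0                      # count-mode NB size

    def __post_init__(self) -> None:
        if self.taxon_group not in _TAXON_SCALE:
            raise ValueError(f"unknown taxon_group {self.taxon_group!r}")
        if self.n_sources < 1 or self.distances_per_study[0] < 2:
            raise ValueError("need >= 1 source and >= 2 distances per study")
        if self.sd_missing_rate is None:
            self.sd_missing_rate = _TAXON_SCALE[self.taxon_group][2]
        if self.zero_rate_target is None:
            self.zero_rate_target = _TAXON_SCALE[self.taxon_group][1]
        if not (0 <= self.sd_missing_rate <= 1
                and 0 <= self.zero_rate_target < 1):
            raise ValueError("rates must lie in [0, 1]")
        if any(s < 0 for s in self.true_sigma2):
            raise ValueError("variance components must be >= 0")
        if self.true_terms is None:
            ref = REFERENCE_COEFFICIENTS[self.taxon_group]
            self.true_terms = tuple(ref["terms"])
            if self.true_beta is None:
                self.true_beta = tuple(ref["beta"])
        if self.true_beta is None:
            raise ValueError("true_beta required with custom true_terms")

    @property
    def spec(self) -> ModeratorSpec:
        return ModeratorSpec(self.true_terms)


def taxon_preset(taxon_group: str, seed: int = 0, **overrides) -> SimulationConfig:
    """Config whose expected record count matches the published database."""
    target = _TAXON_SCALE[taxon_group][0]
    # expected records/source: E[studies] * E[species] * E[treat distances]
    exp = 2.0 * 3.5 * 2.5
    return SimulationConfig(
        seed=seed, taxon_group=taxon_group,
        n_sources=max(1, round(target / exp)), **overrides)


@dataclasses.dataclass
class SimulatedDataset:
    comparisons: pd.DataFrame
    truth: dict

    def write(self, csv_path, truth_path) -> None:
        import json
        data_model.write_comparisons(self.comparisons, csv_path)
        serializable = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.truth.items()}
        with open(truth_path, "w") as fh:
            json.dump(serializable, fh, indent=1)


def _site_cv(config: SimulationConfig) -> float:
    """Within-site coefficient of variation implied by the zero-mean target.

    A site mean observed as Normal(mu, cv*mu/sqrt(n)) censored at zero is
    zero with probability Phi(-sqrt(n)/cv); the target refers to either
    side of a comparison being zero, hence the square-root complement.
    An explicit ``site_cv`` bypasses the calibration (used by recovery
    experiments that need the lognormal sampling model to hold well).
    """
    if config.site_cv is not None:
        return float(config.site_cv)
    p_site = 1.0 - np.sqrt(1.0 - config.zero_rate_target)
    if p_site <= 0:
        return 0.5
    n_bar = np.mean(config.within_site_n)
    return float(np.sqrt(n_bar) / -scipy.stats.norm.ppf(p_site))


def _observe_site(rng, true_mean, n, D, cv_gamma_shape, cv_bar, config):
    """Observed (mean, sd) for one site."""
    if not config.within_site_noise:
        return float(true_mean), 0.0
    cv = rng.gamma(cv_gamma_shape, cv_bar / cv_gamma_shape)
    if config.count_mode:
        lam = true_mean * D
        p = config.nb_dispersion / (config.nb_dispersion + lam)
        reps = rng.negative_binomial(config.nb_dispersion, p, size=n) / D
        return float(reps.mean()), float(reps.std(ddof=1)) if n > 1 else 0.0
    # abundances derive from counts over n*D sampling units, so observed
    # means are multiples of 1/(n*D); rounding reproduces exact zeros and
    # keeps near-zero means away from the continuum
    resolution = 1.0 / (n * D)
    draw = rng.normal(true_mean, cv * true_mean / np.sqrt(n))
    mean_obs = max(round(draw / resolution) * resolution, 0.0)
    # reported dispersion tracks the reported level, as in count-derived
    # abundance metrics; the truncated-mean floor keeps zero-mean sites'
    # SDs on the scale of the detection limit
    sd_level = max(mean_obs, 0.5 * resolution)
    sd_obs = cv * sd_level
    if n > 1:
        sd_obs *= np.sqrt(rng.chisquare(n - 1) / (n - 1))
    return float(mean_obs), float(sd_obs)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Draw one dataset; byte-reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    taxon = config.taxon_group
    noncarn_share = _TAXON_SCALE[taxon][3]
    cv_bar = _site_cv(config)
    cv_shape = 4.0

    # species pool with traits and clade membership
    n_pool = max(config.n_clades * 6, 30)
    bm_mu, bm_sd = _BM_DIST[taxon]
    pool = pd.DataFrame({
        "species_id": [f"sp{i:04d}" for i in range(n_pool)],
        "clade": [f"clade{rng.integers(config.n_clades):02d}"
                  for _ in range(n_pool)],
        "body_mass_g": 10.0 ** rng.normal(bm_mu, bm_sd, n_pool),
    })
    if noncarn_share is not None:
        carn = rng.random(n_pool) >= noncarn_share
        pool["diet_pct"] = np.where(carn, rng.uniform(0, 100, n_pool), 0.0)
    else:
        pool["diet_pct"] = np.nan

    u_clade = {c: rng.normal(0, np.sqrt(config.true_sigma2[1]))
               for c in pool["clade"].unique()}
    u_species = {s: rng.normal(0, np.sqrt(config.true_sigma2[2]))
                 for s in pool["species_id"]}

    infra_levels = ["paved_road", "unpaved_road", "power_line", "non_traffic"]
    infra_probs = [0.53, 0.20, 0.10, 0.17]

    rows, true_lrrs = [], []
    comp = 0
    for si in range(config.n_sources):
        source_id = f"src{si:03d}"
        u_source = rng.normal(0, np.sqrt(config.true_sigma2[3]))
        n_studies = rng.integers(config.studies_per_source[0],
                                 config.studies_per_source[1] + 1)
        for st in range(n_studies):
            study_id = f"{source_id}_st{st}"
            u_study = rng.normal(0, np.sqrt(config.true_sigma2[4]))
            habitat = "open" if rng.random() < config.open_habitat_share \
                else "closed"
            infra = infra_levels[rng.choice(4, p=infra_probs)]
            if taxon != "bird" and infra == "power_line":
                infra = "non_traffic"
            n_dist = rng.integers(config.distances_per_study[0],
                                  config.distances_per_study[1] + 1)
            dists = np.sort(10.0 ** rng.uniform(
                0, np.log10(config.max_distance_m), n_dist))
            if rng.random() < 0.10:
                dists[0] = 0.0          # occasional on-infrastructure site
            ctrl_d, treat_ds = dists[-1], dists[:-1]
            D = 1.0 if rng.random() < 0.8 else float(rng.integers(10, 101))
            n_sp = rng.integers(config.species_per_study[0],
                                config.species_per_study[1] + 1)
            chosen = pool.iloc[rng.choice(n_pool, size=n_sp, replace=False)]
            for _, sp in chosen.iterrows():
                ctrl_true = float(rng.lognormal(*config.control_mean_scale))
                n_ctrl = int(rng.integers(config.within_site_n[0],
                                          config.within_site_n[1] + 1))
                mean_c, sd_c = _observe_site(
                    rng, ctrl_true, n_ctrl, D, cv_shape, cv_bar, config)
                for d in treat_ds:
                    frame = pd.DataFrame({
                        "distance_m": [d],
                        "diet_pct": [0.0 if np.isnan(sp["diet_pct"])
                                     else sp["diet_pct"]],
                        "body_mass_g": [sp["body_mass_g"]],
                        "habitat": [habitat], "infra_type": [infra]})
                    X, _ = build_design(frame, config.spec, taxon)
                    u_obs = rng.normal(0, np.sqrt(config.true_sigma2[0]))
                    lrr = float(X[0] @ np.asarray(config.true_beta)) + \
                        u_clade[sp["clade"]] + u_species[sp["species_id"]] + \
                        u_source + u_study + u_obs
                    treat_true = ctrl_true * np.exp(lrr)
                    n_treat = int(rng.integers(config.within_site_n[0],
                                               config.within_site_n[1] + 1))
                    mean_t, sd_t = _observe_site(
                        rng, treat_true, n_treat, D, cv_shape, cv_bar, config)
                    rows.append({
                        "comparison_id": f"c{comp:05d}",
                        "source_id": source_id, "study_id": study_id,
                        "species_id": sp["species_id"], "taxon_group": taxon,
                        "clade": sp["clade"], "distance_m": d,
                        "infra_type": infra, "habitat": habitat,
                        "mean_treat": mean_t,
                        "sd_treat": np.nan if config.within_site_noise
                        and rng.random() < config.sd_missing_rate else sd_t,
                        "n_treat": n_treat,
                        "mean_ctrl": mean_c,
                        "sd_ctrl": np.nan if config.within_site_noise
                        and rng.random() < config.sd_missing_rate else sd_c,
                        "n_ctrl": n_ctrl,
                        "scale_D": D,
                        "body_mass_g": sp["body_mass_g"],
                        "diet_pct": sp["diet_pct"],
                        "quality_a": int(rng.random() < 0.97),
                        "quality_b": int(rng.random() < 0.40),
                    })
                    true_lrrs.append(lrr)
                    comp += 1
    if not rows:
        raise ValueError("infeasible configuration: no records generated")
    comparisons = pd.DataFrame(rows)
    truth = {
        "true_terms": list(config.true_terms),
        "true_beta": list(config.true_beta),
        "true_sigma2": list(config.true_sigma2),
        "true_lrr": np.asarray(true_lrrs),
    }
    return SimulatedDataset(comparisons=comparisons, truth=truth)


# ---------------------------------------------------------------------------
# Parameter-recovery experiments

@dataclasses.dataclass
class RecoveryReport:
    """Per-replicate estimates from repeated simulate-and-refit runs."""

    estimates: pd.DataFrame           # rep, term, estimate, se, covered, true
    sigma2: pd.DataFrame              # rep, component, estimate, true

    def summary(self) -> pd.DataFrame:
        g = self.estimates.groupby("term", sort=False)
        out = pd.DataFrame({
            "true": g["true"].first(),
            "bias": g.apply(
                lambda d: (d["estimate"] - d["true"]).mean(),
                include_groups=False),
            "rmse": g.apply(
                lambda d: np.sqrt(((d["estimate"] - d["true"])**2).mean()),
                include_groups=False),
            "coverage": g["covered"].mean(),
        })
        return out.reset_index()

    def sigma2_summary(self) -> pd.DataFrame:
        g = self.sigma2.groupby("component", sort=False)
        out = pd.DataFrame({
            "true": g["true"].first(),
            "mean_estimate": g["estimate"].mean(),
            "median_estimate": g["estimate"].median(),
        })
        out["relative_bias"] = np.where(
            out["true"] > 0,
            (out["mean_estimate"] - out["true"]) / out["true"], np.nan)
        return out.reset_index()


def recovery_experiment(
    config: SimulationConfig,
    n_reps: int,
    *,
    imputation: str = "poisson",
    multistart: bool = False,
) -> RecoveryReport:
    """Simulate, impute, build effect sizes and refit the true model.

    Each replicate re-derives the dataset from ``config.seed + rep``, runs
    the standard pipeline stages and fits the generating specification by
    REML, recording coefficient estimates, Wald 95% CI coverage of the
    truth, and the variance-component estimates.
    """
    from .effect_sizes import build_effect_size_set, impute_sd
    from .meta_design import RandomEffectsSpec
    from .meta_engine import fit_model

    re_spec = RandomEffectsSpec()
    beta_rows, s2_rows = [], []
    for rep in range(n_reps):
        cfg = dataclasses.replace(config, seed=config.seed + rep)
        sim = simulate_dataset(cfg)
        df = impute_sd(sim.comparisons, imputation, seed=cfg.seed)
        eset = build_effect_size_set(df)
        model = fit_model(eset, cfg.spec, re_spec, cfg.taxon_group,
                          multistart=multistart, with_stats=False)
        for j, term in enumerate(model.beta_labels):
            true_b = config.true_beta[j]
            beta_rows.append({
                "rep": rep, "term": term, "estimate": model.beta[j],
                "se": model.se[j], "true": true_b,
                "covered": bool(model.ci_low[j] <= true_b
                                <= model.ci_high[j])})
        for k, comp in enumerate(model.sigma2_labels):
            s2_rows.append({"rep": rep, "component": comp,
                            "estimate": model.sigma2[k],
                            "true": config.true_sigma2[k]})
    return RecoveryReport(estimates=pd.DataFrame(beta_rows),
                          sigma2=pd.DataFrame(s2_rows))
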