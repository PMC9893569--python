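"""Synthetic household-survey generator with a fully known utilisation model.

Emulates the statistical structure of Brazil's national household health
surveys (PNAD / PNS): skewed household income per capita (log-normal within
each of five regions, with region-specific location shifts), heterogeneous
survey weights, household clustering, and binary health-care-utilisation
outcomes produced by a latent model whose covariates (insurance, education,
need factors) are themselves correlated with the income rank.  Because the
generating model is returned alongside the data (:class:`GeneratorTruth`),
downstream estimators can be checked against analytic or simulation-based
ground truth — e.g. an outcome with utilisation probability ``p = a + b R``
in the fractional rank ``R`` has expected Erreygers index ``2 b / 3``, since
``E = 8 cov(h, R) = 8 b Var(R)`` and the weighted rank distribution is
uniform with variance 1/12.

Persons are independent given their covariates; within-household outcome
correlation beyond shared income/region is not modelled.  Stratum and PSU
identifiers (region x income-tercile blocks of households) exist to exercise
clustered bootstrap machinery, not to replicate IBGE's three-stage design.

Randomness is organised as one stream per component (households/income,
demographics, weights, one per covariate, one per outcome), each derived
deterministically from the config seed, so declaring an extra covariate does
not perturb the incomes already generated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .data import SurveyMicrodata
from .exceptions import ConfigurationError
from .ranking import fractional_rank

__all__ = [
    "RegionSpec",
    "CovariateSpec",
    "Eligibility",
    "OutcomeSpec",
    "GeneratorConfig",
    "OutcomeTruth",
    "GeneratorTruth",
    "generate",
    "default_config",
]

DEFAULT_REGION_LABELS = ("North", "North-East", "South-East", "South", "Midwest")


@dataclass(frozen=True)
class RegionSpec:
    """One major region: population share and log-normal income parameters."""

    label: str
    share: float
    income_log_mean: float  # location of log(income per capita)
    income_log_sd: float = 0.9


@dataclass(frozen=True)
class CovariateSpec:
    """A covariate definition with optional dependence on the income rank.

    Binary covariates follow ``P(x = 1 | R) = expit(rank_intercept +
    rank_slope * R)``; continuous ones follow ``x = rank_intercept +
    rank_slope * R + Normal(0, noise_sd)``; categorical ones draw from
    ``levels`` with fixed ``level_probs`` (no rank dependence).  A zero
    ``rank_slope`` makes the covariate independent of income.
    """

    name: str
    role: str  # predisposing | enabling | need
    kind: str  # binary | continuous | categorical
    rank_slope: float = 0.0
    rank_intercept: float = 0.0
    noise_sd: float = 1.0
    levels: tuple = ()
    level_probs: tuple = ()


@dataclass(frozen=True)
class Eligibility:
    """Restriction of an outcome's denominator, e.g. women aged 50-69."""

    sex: Optional[str] = None
    age_min: Optional[float] = None
    age_max: Optional[float] = None

    def mask(self, sex: np.ndarray, age: np.ndarray) -> np.ndarray:
        ok = np.ones(sex.shape[0], dtype=bool)
        if self.sex is not None:
            ok &= sex == self.sex
        if self.age_min is not None:
            ok &= age >= self.age_min
        if self.age_max is not None:
            ok &= age <= self.age_max
        return ok


@dataclass(frozen=True)
class OutcomeSpec:
    """A binary utilisation outcome and its latent model.

    ``model`` is one of

    * ``"probit"`` — ``P = Phi(intercept + rank_coef * R + sum_j c_j x_j)``;
    * ``"linear_rank"`` — probability directly linear in the rank,
      ``P = intercept + rank_coef * R + sum_j c_j x_j`` (must stay in [0, 1]:
      escaping probabilities are an error, never clipped);
    * ``"constant"`` — ``P = intercept``.

    ``coefficients`` maps covariate names (or ``name[level]`` for a
    categorical level indicator) to coefficients.  ``delivery_fraction``, if
    set, marks that share of positive cases among women aged 18-49 as
    delivery-only admissions in a companion ``<name>_delivery_only`` column
    (for hospitalisation outcomes, where the analysis recodes such admissions
    to non-use).
    """

    name: str
    model: str = "probit"
    intercept: float = 0.0
    rank_coef: float = 0.0
    coefficients: dict = field(default_factory=dict)
    eligibility: Optional[Eligibility] = None
    delivery_fraction: Optional[float] = None


@dataclass(frozen=True)
class GeneratorConfig:
    n_persons: int
    seed: int
    regions: tuple = ()
    weight_model: str = "gamma"  # "gamma" (mean 1) | "uniform" (all 1)
    weight_gamma_shape: float = 4.0
    household_size_range: tuple = (1, 6)
    covariates: tuple = ()
    outcomes: tuple = ()
    female_share: float = 0.52
    age_max: float = 95.0
    psu_households: int = 25

    def validate(self) -> "GeneratorConfig":
        if self.n_persons < 2:
            raise ConfigurationError("n_persons must be at least 2")
        if not self.regions:
            raise ConfigurationError("regions must declare at least one region")
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("regions: labels must be unique")
        shares = np.array([r.share for r in self.regions], dtype=float)
        if (shares <= 0).any() or abs(shares.sum() - 1.0) > 1e-9:
            raise ConfigurationError("regions: shares must be positive and sum to 1")
        if self.weight_model not in ("gamma", "uniform"):
            raise ConfigurationError(
                f"weight_model: unknown model {self.weight_model!r}"
            )
        lo, hi = self.household_size_range
        if not (1 <= lo <= hi):
            raise ConfigurationError("household_size_range must satisfy 1 <= lo <= hi")
        declared = set()
        for cov in self.covariates:
            if cov.kind not in ("binary", "continuous", "categorical"):
                raise ConfigurationError(f"covariate_spec[{cov.name}]: bad kind {cov.kind!r}")
            if cov.role not in ("predisposing", "enabling", "need"):
                raise ConfigurationError(f"covariate_spec[{cov.name}]: bad role {cov.role!r}")
            if cov.name in declared:
                raise ConfigurationError(f"covariate_spec: duplicate name {cov.name!r}")
            declared.add(cov.name)
            if cov.kind == "categorical":
                if len(cov.levels) < 2 or len(cov.levels) != len(cov.level_probs):
                    raise ConfigurationError(
                        f"covariate_spec[{cov.name}]: categorical needs matching "
                        "levels and level_probs"
                    )
                for lv in cov.levels:
                    declared.add(f"{cov.name}[{lv}]")
        out_names = set()
        for out in self.outcomes:
            if out.model not in ("probit", "linear_rank", "constant"):
                raise ConfigurationError(
                    f"outcome_spec[{out.name}]: unknown model {out.model!r}"
                )
            if out.name in out_names:
                raise ConfigurationError(f"outcome_spec: duplicate name {out.name!r}")
            out_names.add(out.name)
            for key in out.coefficients:
                if key not in declared:
                    raise ConfigurationError(
                        f"outcome_spec[{out.name}]: coefficient refers to "
                        f"undeclared covariate {key!r}"
                    )
        return self


@dataclass(frozen=True)
class OutcomeTruth:
    """The exact latent model used for one outcome."""

    model: str
    intercept: float
    rank_coef: float
    coefficients: dict
    rank_gradient: float  # marginal dependence of P(use) on the income rank
    expected_erreygers: Optional[float]  # closed form when derivable, else None


@dataclass(frozen=True)
class GeneratorTruth:
    """Ground truth for every generated outcome, for oracle-style tests."""

    outcomes: dict  # name -> OutcomeTruth

    def to_json(self, path) -> None:
        payload = {k: asdict(v) for k, v in self.outcomes.items()}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


def default_config(n_persons: int = 100_000, seed: int = 0) -> GeneratorConfig:
    """A five-region configuration emulating a recent national health survey.

    Region shares follow the rough population split of Brazil's five major
    regions, with poorer North/North-East income locations; insurance and
    secondary education are enabling covariates concentrated among the rich;
    a chronic-condition indicator is the need factor, slightly concentrated
    among the poor.  Outcomes cover outpatient care (doctor visit),
    need-based inpatient care (hospitalisation, with a delivery-only flag for
    recoding), and the two screening services with their age/sex eligibility
    windows.
    """
    regions = (
        RegionSpec("North", 0.08, np.log(900.0)),
        RegionSpec("North-East", 0.27, np.log(800.0)),
        RegionSpec("South-East", 0.42, np.log(1500.0)),
        RegionSpec("South", 0.14, np.log(1400.0)),
        RegionSpec("Midwest", 0.09, np.log(1200.0)),
    )
    covariates = (
        CovariateSpec("insurance", "enabling", "binary", rank_slope=3.0, rank_intercept=-2.8),
        CovariateSpec("secondary_education", "enabling", "binary", rank_slope=2.2, rank_intercept=-1.0),
        CovariateSpec("employed", "predisposing", "binary", rank_slope=0.8, rank_intercept=-0.2),
        CovariateSpec("chronic_ncd", "need", "binary", rank_slope=-0.4, rank_intercept=-0.7),
    )
    outcomes = (
        OutcomeSpec(
            "doctor_visit",
            model="probit",
            intercept=0.45,
            rank_coef=0.5,
            coefficients={"insurance": 0.45, "chronic_ncd": 0.5},
        ),
        OutcomeSpec(
            "hospitalisation",
            model="probit",
            intercept=-1.65,
            rank_coef=0.1,
            coefficients={"insurance": 0.12, "chronic_ncd": 0.45},
            delivery_fraction=0.2,
        ),
        OutcomeSpec(
            "pap_smear",
            model="probit",
            intercept=0.5,
            rank_coef=0.5,
            coefficients={"insurance": 0.4, "secondary_education": 0.3},
            eligibility=Eligibility(sex="female", age_min=25, age_max=59),
        ),
        OutcomeSpec(
            "mammogram",
            model="probit",
            intercept=-0.6,
            rank_coef=0.9,
            coefficients={"insurance": 0.55, "secondary_education": 0.35},
            eligibility=Eligibility(sex="female", age_min=50, age_max=69),
        ),
    )
    return GeneratorConfig(
        n_persons=n_persons,
        seed=seed,
        regions=regions,
        covariates=covariates,
        outcomes=outcomes,
    )


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([seed, *key])


_HOUSEHOLD, _DEMOGRAPHICS, _WEIGHTS, _COVARIATE, _OUTCOME = 1, 2, 3, 10, 20


def _covariate_matrix(df: pd.DataFrame, config: GeneratorConfig) -> dict:
    cols = {}
    for cov in config.covariates:
        if cov.kind == "categorical":
            for lv in cov.levels:
                cols[f"{cov.name}[{lv}]"] = (df[cov.name] == lv).to_numpy(float)
        else:
            cols[cov.name] = df[cov.name].to_numpy(float)
    return cols


def generate(config: GeneratorConfig):
    """Draw one synthetic survey; returns ``(SurveyMicrodata, GeneratorTruth)``.

    Deterministic for a fixed seed.  Probabilities escaping [0, 1] under a
    linear-in-rank outcome model raise :class:`ConfigurationError` — they are
    never clipped.
    """
    config.validate()
    seed = config.seed
    n = config.n_persons

    # --- households: size, region, income per capita, weight -------------
    hh_rng = _rng(seed, _HOUSEHOLD)
    lo, hi = config.household_size_range
    max_hh = n if lo == 1 else n // lo + 2
    sizes = hh_rng.integers(lo, hi + 1, size=max_hh)
    cum = np.cumsum(sizes)
    n_hh = int(np.searchsorted(cum, n)) + 1
    sizes = sizes[:n_hh]
    sizes[-1] -= cum[n_hh - 1] - n  # truncate the last household to hit n
    if sizes[-1] == 0:
        sizes = sizes[:-1]
        n_hh -= 1

    shares = np.array([r.share for r in config.regions])
    region_idx_hh = hh_rng.choice(len(config.regions), size=n_hh, p=shares)
    mu = np.array([r.income_log_mean for r in config.regions])[region_idx_hh]
    sd = np.array([r.income_log_sd for r in config.regions])[region_idx_hh]
    income_hh = np.exp(hh_rng.normal(mu, sd))

    w_rng = _rng(seed, _WEIGHTS)
    if config.weight_model == "gamma":
        shape = config.weight_gamma_shape
        weight_hh = w_rng.gamma(shape, 1.0 / shape, size=n_hh)
    else:
        weight_hh = np.ones(n_hh)

    hh_of_person = np.repeat(np.arange(n_hh), sizes)
    region_labels = np.array([r.label for r in config.regions])
    df = pd.DataFrame(
        {
            "person_id": np.arange(hh_of_person.shape[0]),
            "household_id": hh_of_person,
            "income_pc": income_hh[hh_of_person],
            "weight": weight_hh[hh_of_person],
            "region": region_labels[region_idx_hh[hh_of_person]],
        }
    )

    # --- demographics ----------------------------------------------------
    demo_rng = _rng(seed, _DEMOGRAPHICS)
    n = len(df)
    df["age"] = 18.0 + (config.age_max - 18.0) * demo_rng.beta(1.2, 1.8, size=n)
    df["sex"] = np.where(
        demo_rng.random(n) < config.female_share, "female", "male"
    )

    # --- weighted income ranks drive covariate/outcome dependence --------
    ranked = fractional_rank(df["income_pc"].to_numpy(), df["weight"].to_numpy())
    R = ranked.ranks

    # --- stratum / PSU: region x weighted income tercile, household blocks
    tercile = np.minimum((R * 3).astype(int), 2)
    df["stratum_id"] = df["region"].astype(str) + "-T" + tercile.astype(str)
    # deterministic PSU blocks of households within each stratum
    hh_stratum = pd.Series(df["stratum_id"].to_numpy(), index=df.index).groupby(
        df["household_id"]
    ).first()
    block = np.zeros(n_hh, dtype=int)
    for s in hh_stratum.unique():
        ids = hh_stratum.index[hh_stratum == s].to_numpy()
        block[ids] = np.arange(ids.shape[0]) // config.psu_households
    df["psu_id"] = df["stratum_id"] + "-P" + block[df["household_id"]].astype(str)

    # --- covariates ------------------------------------------------------
    covariate_roles = {}
    for j, cov in enumerate(config.covariates):
        rng = _rng(seed, _COVARIATE, j)
        if cov.kind == "binary":
            p = expit(cov.rank_intercept + cov.rank_slope * R)
            df[cov.name] = (rng.random(n) < p).astype(float)
        elif cov.kind == "continuous":
            df[cov.name] = (
                cov.rank_intercept
                + cov.rank_slope * R
                + rng.normal(0.0, cov.noise_sd, size=n)
            )
        else:
            df[cov.name] = rng.choice(
                list(cov.levels), size=n, p=list(cov.level_probs)
            )
        covariate_roles[cov.name] = cov.role

    # --- outcomes --------------------------------------------------------
    xcols = _covariate_matrix(df, config)
    truth_outcomes = {}
    outcome_names = []
    sex = df["sex"].to_numpy()
    age = df["age"].to_numpy()
    rank_independent = {
        cov.name: cov.rank_slope == 0.0 or cov.kind == "categorical"
        for cov in config.covariates
    }
    for j, out in enumerate(config.outcomes):
        rng = _rng(seed, _OUTCOME, j)
        lin = np.zeros(n)
        for key, coef in out.coefficients.items():
            lin += coef * xcols[key]
        if out.model == "probit":
            eta = out.intercept + out.rank_coef * R + lin
            p = stats.norm.cdf(eta)
            gradient = float(np.average(out.rank_coef * stats.norm.pdf(eta), weights=df["weight"]))
        elif out.model == "linear_rank":
            p = out.intercept + out.rank_coef * R + lin
            gradient = out.rank_coef
        else:  # constant
            p = np.full(n, out.intercept)
            gradient = 0.0
        if (p < 0).any() or (p > 1).any():
            raise ConfigurationError(
                f"outcome_spec[{out.name}]: model probabilities escape [0, 1] "
                f"(min {p.min():.4f}, max {p.max():.4f}); refusing to clip"
            )
        h = (rng.random(n) < p).astype(float)
        if out.eligibility is not None:
            eligible = out.eligibility.mask(sex, age)
            h = np.where(eligible, h, np.nan)
        df[out.name] = h
        outcome_names.append(out.name)

        if out.delivery_fraction is not None:
            candidates = (
                (h == 1.0) & (sex == "female") & (age >= 18) & (age <= 49)
            )
            flag = np.zeros(n)
            flag[candidates] = (
                rng.random(int(candidates.sum())) < out.delivery_fraction
            ).astype(float)
            df[f"{out.name}_delivery_only"] = flag

        if out.model == "constant":
            expected = 0.0
        elif out.model == "linear_rank" and not out.coefficients:
            expected = 2.0 * out.rank_coef / 3.0
        elif (
            out.model == "probit"
            and out.rank_coef == 0.0
            and all(
                rank_independent.get(key.split("[")[0], False)
                for key in out.coefficients
            )
        ):
            expected = 0.0
        else:
            expected = None
        truth_outcomes[out.name] = OutcomeTruth(
            model=out.model,
            intercept=out.intercept,
            rank_coef=out.rank_coef,
            coefficients=dict(out.coefficients),
            rank_gradient=gradient,
            expected_erreygers=expected,
        )

    data = SurveyMicrodata(
        table=df, covariate_roles=covariate_roles, outcomes=outcome_names
    ).validate()
    return data, GeneratorTruth(outcomes=truth_outcomes)


def generator_config_from_dict(d: dict) -> GeneratorConfig:
    """Build a :class:`GeneratorConfig` from a plain (YAML-loaded) dict."""
    regions = tuple(
        RegionSpec(**r) for r in d.get("regions", [])
    ) or default_config().regions
    covariates = tuple(
        CovariateSpec(**{**c, "levels": tuple(c.get("levels", ())),
                         "level_probs": tuple(c.get("level_probs", ()))})
        for c in d.get("covariates", [])
    )
    outcomes = []
    for o in d.get("outcomes", []):
        o = dict(o)
        elig = o.pop("eligibility", None)
        outcomes.append(
            OutcomeSpec(**o, eligibility=Eligibility(**elig) if elig else None)
        )
    kwargs = {
        k: d[k]
        for k in (
            "n_persons",
            "seed",
            "weight_model",
            "weight_gamma_shape",
            "female_share",
            "age_max",
            "psu_households",
        )
        if k in d
    }
    if "household_size_range" in d:
        kwargs["household_size_range"] = tuple(d["household_size_range"])
    cfg = GeneratorConfig(
        regions=regions, covariates=covariates, outcomes=tuple(outcomes), **kwargs
    )
    if not cfg.covariates and not d.get("covariates"):
        base = default_config(cfg.n_persons, cfg.seed)
        cfg = GeneratorConfig(
            n_persons=cfg.n_persons,
            seed=cfg.seed,
            regions=cfg.regions,
            weight_model=cfg.weight_model,
            weight_gamma_shape=cfg.weight_gamma_shape,
            household_size_range=cfg.household_size_range,
            covariates=base.covariates,
            outcomes=cfg.outcomes or base.outcomes,
            female_share=cfg.female_share,
            age_max=cfg.age_max,
            psu_households=cfg.psu_households,
        )
    return cfg.validate()
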