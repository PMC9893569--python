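"""End-to-end study driver: eligibility filters, prevalence, indices, decomposition.

Runs the full inequality analysis over one or more survey waves: each wave is
either read from disk (CSV/Parquet + column mapping) or drawn from the
synthetic generator; per outcome the pipeline restricts the denominator to
the eligible population (screening outcomes to their age/sex windows, every
analysis to adults), recodes delivery-only admissions to non-use rather than
dropping the rows, estimates the weighted prevalence with a design-based
normal-approximation CI, the concentration index with CI / significance
stars / pro-rich-pro-poor classification nationally and within each region,
and a covariate decomposition of the corrected index.

Regional indices re-rank individuals *within* the region, so each region's
index measures within-region inequality (a region-constant outcome has a
regional index of zero however poor the region is nationally).

Everything is deterministic given the config seed; per-wave, per-outcome
bootstrap seeds are derived through ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .concentration import IndexEstimate, classify_inequality, index_ci
from .data import SurveyMicrodata
from .decomposition import CovariateDesign, DecompositionTable, decompose
from .exceptions import ConfigurationError
from .io import read_microdata
from .ranking import fractional_rank
from .synthetic import Eligibility, GeneratorConfig, generate

logger = logging.getLogger("healthineq")

__all__ = [
    "EligibilityRule",
    "FilterLog",
    "WaveSource",
    "StudyConfig",
    "StudyReport",
    "default_eligibility_rules",
    "eligibility_filter",
    "weighted_prevalence",
    "run_study",
    "render_report",
]


@dataclass(frozen=True)
class EligibilityRule:
    """Denominator restriction and optional outcome recode for one outcome.

    ``recode_zero_where`` names a 0/1 column; rows where it is 1 have the
    outcome recoded to 0 but stay in the denominator (used for admissions
    that were for labour and delivery only).
    """

    sex: Optional[str] = None
    age_min: Optional[float] = None
    age_max: Optional[float] = None
    recode_zero_where: Optional[str] = None


def default_eligibility_rules() -> dict:
    """Screening windows from national guidelines plus the delivery recode:
    Pap smears for women 25-59, mammograms for women 50-69, hospitalisation
    recoded to exclude delivery-only admissions."""
    return {
        "pap_smear": EligibilityRule(sex="female", age_min=25, age_max=59),
        "mammogram": EligibilityRule(sex="female", age_min=50, age_max=69),
        "hospitalisation": EligibilityRule(
            recode_zero_where="hospitalisation_delivery_only"
        ),
    }


@dataclass
class FilterLog:
    outcome: str
    rows_in: int
    rows_retained: int
    rows_excluded: int
    rows_recoded: int = 0

    def __post_init__(self):
        if self.rows_in != self.rows_retained + self.rows_excluded:
            raise AssertionError("filter log does not conserve row counts")


def eligibility_filter(
    data: SurveyMicrodata,
    outcome_name: str,
    rule: Optional[EligibilityRule] = None,
    min_age: float = 18.0,
):
    """Restrict the denominator for one outcome; returns ``(filtered, log)``.

    Retained rows satisfy the adult age floor, the rule's sex/age window,
    and carry a non-missing outcome.  The recode (delivery-only admission to
    0) is applied before filtering and never drops a row by itself.
    """
    if outcome_name not in data.table.columns:
        raise KeyError(f"outcome column {outcome_name!r} absent from data")
    rule = rule or EligibilityRule()
    df = data.table
    recoded = 0
    if rule.recode_zero_where is not None:
        if rule.recode_zero_where not in df.columns:
            raise KeyError(
                f"recode column {rule.recode_zero_where!r} required by the "
                f"eligibility rule for {outcome_name!r} is absent"
            )
        flag = df[rule.recode_zero_where].to_numpy(float) == 1.0
        hit = flag & (df[outcome_name].to_numpy(float) == 1.0)
        recoded = int(hit.sum())
        if recoded:
            df = df.copy()
            df.loc[hit, outcome_name] = 0.0
            data = SurveyMicrodata(df, dict(data.covariate_roles), list(data.outcomes))

    age = df["age"].to_numpy(float)
    sex = df["sex"].to_numpy()
    keep = age >= min_age
    keep &= Eligibility(rule.sex, rule.age_min, rule.age_max).mask(sex, age)
    keep &= ~df[outcome_name].isna().to_numpy()

    log = FilterLog(
        outcome=outcome_name,
        rows_in=len(df),
        rows_retained=int(keep.sum()),
        rows_excluded=int((~keep).sum()),
        rows_recoded=recoded,
    )
    return data.subset(keep), log


def weighted_prevalence(h, weights, ci_level: float = 0.95):
    """Survey-weighted prevalence with a design-based normal-approximation CI.

    Returns ``(p, se, ci_low, ci_high)``; the SE is the weighted ratio-mean
    standard error ``sqrt(sum w_i^2 (h_i - p)^2) / W``.
    """
    h = np.asarray(h, float)
    w = np.asarray(weights, float)
    W = w.sum()
    p = float(np.sum(w * h) / W)
    se = float(np.sqrt(np.sum((w * (h - p)) ** 2)) / W)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    return p, se, max(p - z * se, 0.0), min(p + z * se, 1.0)


@dataclass
class WaveSource:
    """One survey wave: either a file (+ mapping) or a generator config."""

    year: int
    path: Optional[str] = None
    mapping: Optional[object] = None
    generator: Optional[GeneratorConfig] = None

    def load(self) -> SurveyMicrodata:
        if (self.path is None) == (self.generator is None):
            raise ConfigurationError(
                f"wave {self.year}: exactly one of path or generator must be set"
            )
        if self.path is not None:
            return read_microdata(self.path, self.mapping)
        data, _ = generate(self.generator)
        return data


@dataclass
class StudyConfig:
    waves: list
    outcomes: Optional[list] = None  # default: every outcome the data declares
    eligibility: dict = field(default_factory=default_eligibility_rules)
    min_age: float = 18.0
    variant: str = "erreygers"
    ci_method: str = "robust_regression"
    ci_level: float = 0.95
    n_boot: int = 500
    seed: Optional[int] = None
    by_region: bool = True
    decompose_years: Optional[list] = None  # default: most recent wave only
    design_columns: Optional[list] = None  # default: all declared covariates
    include_region_effects: bool = True
    include_income_quintiles: bool = True
    reference_region: Optional[str] = None
    share_floor: float = 0.01
    row_filters: list = field(default_factory=list)  # [{"column", "op", "value"}]

    def validate(self) -> "StudyConfig":
        years = [w.year for w in self.waves]
        if len(set(years)) != len(years):
            raise ConfigurationError("waves: years must be unique")
        if self.ci_method == "bootstrap" and self.seed is None:
            raise ConfigurationError("seed: required when ci_method is 'bootstrap'")
        if self.variant not in ("standard", "erreygers", "wagstaff"):
            raise ConfigurationError(f"variant: unknown {self.variant!r}")
        for f in self.row_filters:
            if not {"column", "op", "value"} <= set(f):
                raise ConfigurationError(
                    "row_filters: each rule needs column/op/value"
                )
            if f["op"] not in ("==", "!=", "<", "<=", ">", ">="):
                raise ConfigurationError(f"row_filters: unknown op {f['op']!r}")
        return self


@dataclass
class StudyReport:
    prevalence: pd.DataFrame
    indices: pd.DataFrame
    decompositions: dict  # (year, outcome) -> DecompositionTable
    filter_logs: list
    run_log: dict


def _apply_row_filters(data: SurveyMicrodata, rules) -> SurveyMicrodata:
    import operator as op_mod

    ops = {
        "==": op_mod.eq,
        "!=": op_mod.ne,
        "<": op_mod.lt,
        "<=": op_mod.le,
        ">": op_mod.gt,
        ">=": op_mod.ge,
    }
    for rule in rules:
        col = rule["column"]
        if col not in data.table.columns:
            raise ConfigurationError(f"row_filters: column {col!r} absent")
        keep = ops[rule["op"]](data.table[col], rule["value"]).to_numpy(bool)
        data = data.subset(keep)
    return data


def _derived_seed(base: int, *key: int) -> int:
    ss = np.random.SeedSequence([int(base), *key])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _estimate_index(sub: pd.DataFrame, config: StudyConfig, outcome, seed):
    income = sub["income_pc"].to_numpy(float)
    w = sub["weight"].to_numpy(float)
    h = sub[outcome].to_numpy(float)
    ranked = fractional_rank(income, w)
    cluster = sub["psu_id"].to_numpy() if "psu_id" in sub.columns else None
    return index_ci(
        h,
        ranked,
        w,
        variant=config.variant,
        method=config.ci_method,
        ci_level=config.ci_level,
        n_boot=config.n_boot,
        seed=seed,
        cluster_id=cluster,
        income_pc=income,
    )


def _index_row(year, outcome, region, est: IndexEstimate, n_obs):
    return {
        "year": year,
        "outcome": outcome,
        "region": region,
        "variant": est.variant,
        "value": est.value,
        "se": est.se,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "p_value": est.p_value,
        "stars": est.stars,
        "classification": classify_inequality(est),
        "mean_outcome": est.mean_outcome,
        "n": n_obs,
    }


def run_study(config: StudyConfig) -> StudyReport:
    """Run the whole study; deterministic given the config seed.

    A stratum with no eligible rows (or a degenerate index) becomes an empty
    cell with a logged diagnostic rather than a crash.
    """
    config.validate()
    seed = config.seed if config.seed is not None else 0
    prevalence_rows, index_rows, decomps, filter_logs = [], [], {}, []
    run_log = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": hashlib.sha256(repr(config).encode()).hexdigest()[:16],
        "warnings": [],
    }
    decompose_years = config.decompose_years
    if decompose_years is None and config.waves:
        decompose_years = [max(w.year for w in config.waves)]

    for wi, wave in enumerate(sorted(config.waves, key=lambda w: w.year)):
        data = wave.load()
        data = _apply_row_filters(data, config.row_filters)
        outcomes = config.outcomes or data.outcomes
        for oi, outcome in enumerate(outcomes):
            rule = config.eligibility.get(outcome)
            filtered, flog = eligibility_filter(
                data, outcome, rule, min_age=config.min_age
            )
            flog_rec = {"year": wave.year, **flog.__dict__}
            filter_logs.append(flog_rec)
            if filtered.n == 0:
                run_log["warnings"].append(
                    f"{wave.year}/{outcome}: no eligible rows; cell left empty"
                )
                continue
            sub = filtered.table
            h = sub[outcome].to_numpy(float)
            w = sub["weight"].to_numpy(float)
            p, se, lo, hi = weighted_prevalence(h, w, config.ci_level)
            prevalence_rows.append(
                {
                    "year": wave.year,
                    "outcome": outcome,
                    "n": int(np.sum(h == 1.0)),
                    "n_eligible": filtered.n,
                    "weighted_pct": 100.0 * p,
                    "ci_low_pct": 100.0 * lo,
                    "ci_high_pct": 100.0 * hi,
                }
            )
            try:
                est = _estimate_index(
                    sub, config, outcome, _derived_seed(seed, wi, oi)
                )
                index_rows.append(
                    _index_row(wave.year, outcome, "All", est, filtered.n)
                )
            except Exception as exc:  # isolate per-stratum failures
                run_log["warnings"].append(
                    f"{wave.year}/{outcome}/All: {type(exc).__name__}: {exc}"
                )
            if config.by_region:
                for ri, region in enumerate(sorted(sub["region"].unique())):
                    rsub = sub[sub["region"] == region].reset_index(drop=True)
                    try:
                        est = _estimate_index(
                            rsub,
                            config,
                            outcome,
                            _derived_seed(seed, wi, oi, ri),
                        )
                        index_rows.append(
                            _index_row(wave.year, outcome, region, est, len(rsub))
                        )
                    except Exception as exc:
                        run_log["warnings"].append(
                            f"{wave.year}/{outcome}/{region}: "
                            f"{type(exc).__name__}: {exc}"
                        )
            if wave.year in (decompose_years or []):
                try:
                    decomps[(wave.year, outcome)] = _decompose_wave(
                        filtered, outcome, config
                    )
                except Exception as exc:
                    run_log["warnings"].append(
                        f"{wave.year}/{outcome}/decomposition: "
                        f"{type(exc).__name__}: {exc}"
                    )

    run_log["filter_logs"] = filter_logs
    return StudyReport(
        prevalence=pd.DataFrame(prevalence_rows),
        indices=pd.DataFrame(index_rows),
        decompositions=decomps,
        filter_logs=filter_logs,
        run_log=run_log,
    )


def _decompose_wave(
    filtered: SurveyMicrodata, outcome: str, config: StudyConfig
) -> DecompositionTable:
    sub = filtered.table
    columns = list(config.design_columns or filtered.covariate_roles)
    roles = {c: filtered.covariate_roles.get(c, "enabling") for c in columns}
    categorical = {}
    if config.include_region_effects and sub["region"].nunique() > 1:
        columns.append("region")
        roles["region"] = "enabling"
        categorical["region"] = config.reference_region or sorted(
            sub["region"].unique()
        )[0]
    ranked = fractional_rank(
        sub["income_pc"].to_numpy(float), sub["weight"].to_numpy(float)
    )
    if config.include_income_quintiles:
        # socioeconomic status as weighted income quintile indicators,
        # reference: poorest quintile
        quintile = np.minimum((ranked.ranks * 5).astype(int), 4)
        sub = sub.copy()
        for q in range(2, 6):
            name = f"income_q{q}"
            sub[name] = (quintile == q - 1).astype(float)
            if sub[name].nunique() > 1:
                columns.append(name)
                roles[name] = "enabling"
    design = CovariateDesign.from_frame(
        sub, columns, roles, categorical=categorical
    )
    return decompose(
        sub[outcome].to_numpy(float),
        design,
        ranked,
        sub["weight"].to_numpy(float),
        share_floor=config.share_floor,
    )


# ---------------------------------------------------------------------------
# rendering

_STAR_FOOTNOTE = "*p < 0.1; **p < 0.05; ***p < 0.01"


def _decomp_frame(table: DecompositionTable) -> pd.DataFrame:
    out = table.table.copy().reset_index()
    resid = {
        "covariate": "residual",
        "role": "residual",
        "beta_m": np.nan,
        "averaging_rule": "",
        "gc": table.residual_gc_diagnostic / 4.0,
        "contribution": table.residual_contribution,
        "share": np.nan
        if table.shares_suppressed
        else table.residual_contribution / table.total_index,
    }
    out = pd.concat([out, pd.DataFrame([resid])], ignore_index=True)
    out["total_index"] = table.total_index
    return out


def render_report(report: StudyReport, outdir, formats=("csv_bundle", "json", "markdown")):
    """Write the report as a CSV bundle, JSON, and/or markdown; returns paths."""
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {outdir} is not writable: {exc}") from exc

    written = []
    if "csv_bundle" in formats:
        for name, frame in (
            ("prevalence.csv", report.prevalence),
            ("indices.csv", report.indices),
        ):
            p = outdir / name
            frame.to_csv(p, index=False)
            written.append(p)
        for (year, outcome), table in sorted(report.decompositions.items()):
            p = outdir / f"decomposition_{year}_{outcome}.csv"
            _decomp_frame(table).to_csv(p, index=False)
            written.append(p)

    if "json" in formats:
        payload = {
            "run_log": report.run_log,
            "prevalence": report.prevalence.to_dict(orient="records"),
            "indices": report.indices.to_dict(orient="records"),
            "decompositions": {
                f"{year}/{outcome}": _decomp_frame(t).to_dict(orient="records")
                for (year, outcome), t in sorted(report.decompositions.items())
            },
        }
        p = outdir / "report.json"
        with open(p, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, default=str)
        written.append(p)

    if "markdown" in formats:
        p = outdir / "report.md"
        with open(p, "w", encoding="utf-8") as fh:
            fh.write(_render_markdown(report))
        written.append(p)
    return written


def _render_markdown(report: StudyReport) -> str:
    lines = ["# Health-care utilisation inequality report", ""]
    if len(report.prevalence):
        lines += ["## Prevalence of utilisation", ""]
        frame = report.prevalence.copy()
        frame["weighted_pct"] = frame["weighted_pct"].map(lambda v: f"{v:.1f}")
        frame["95% CI"] = frame.apply(
            lambda r: f"({r.ci_low_pct:.1f}-{r.ci_high_pct:.1f})", axis=1
        )
        lines.append(
            frame[["year", "outcome", "n", "n_eligible", "weighted_pct", "95% CI"]]
            .to_markdown(index=False)
        )
        lines.append("")
    if len(report.indices):
        lines += ["## Concentration indices", ""]
        frame = report.indices.copy()
        frame["index"] = frame.apply(lambda r: f"{r.value:.3f}{r.stars}", axis=1)
        frame["95% CI"] = frame.apply(
            lambda r: f"({r.ci_low:.3f}-{r.ci_high:.3f})", axis=1
        )
        lines.append(
            frame[
                ["year", "outcome", "region", "index", "95% CI", "classification", "n"]
            ].to_markdown(index=False)
        )
        lines += ["", _STAR_FOOTNOTE, ""]
    for (year, outcome), table in sorted(report.decompositions.items()):
        lines += [f"## Decomposition — {outcome} ({year})", ""]
        frame = _decomp_frame(table)
        for col in ("beta_m", "gc", "contribution", "share", "total_index"):
            frame[col] = frame[col].map(
                lambda v: "" if pd.isna(v) else f"{v:.4f}"
            )
        lines.append(frame.to_markdown(index=False))
        lines.append("")
        if table.shares_suppressed:
            lines.append(
                f"Shares suppressed: |E(h)| < {table.share_floor} "
                "(contributions remain valid)."
            )
            lines.append("")
    return "\n".join(lines)


def study_config_from_dict(d: dict) -> StudyConfig:
    """Build a :class:`StudyConfig` from a plain (YAML-loaded) dict."""
    from .synthetic import generator_config_from_dict

    waves = []
    for w in d.get("waves", []):
        gen = w.get("generator")
        waves.append(
            WaveSource(
                year=w["year"],
                path=w.get("path"),
                mapping=w.get("mapping"),
                generator=generator_config_from_dict(gen) if gen else None,
            )
        )
    eligibility = default_eligibility_rules()
    for name, rule in d.get("eligibility", {}).items():
        eligibility[name] = EligibilityRule(**rule)
    kwargs = {
        k: d[k]
        for k in (
            "outcomes",
            "min_age",
            "variant",
            "ci_method",
            "ci_level",
            "n_boot",
            "seed",
            "by_region",
            "decompose_years",
            "design_columns",
            "include_region_effects",
            "reference_region",
            "share_floor",
            "row_filters",
        )
        if k in d
    }
    return StudyConfig(waves=waves, eligibility=eligibility, **kwargs).validate()


def load_study_config(path) -> StudyConfig:
    import yaml

    with open(path, encoding="utf-8") as fh:
        return study_config_from_dict(yaml.safe_load(fh))
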