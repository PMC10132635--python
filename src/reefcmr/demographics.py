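"""Per-site demographic analysis and reporting.

Runs the 30-model Robust Design suite on a site's capture matrix, performs
the goodness-of-fit/overdispersion screen, ranks models by AIC (or QAIC when
any GOF component fails), and summarizes the best model's abundance series
into the derived statistics: per-interval relative change, average annual
growth, and the coefficient of variation of the interval growth ratios (the
stability index).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimator import FitResult, RobustDesignModel, information_criterion
from .gof import GOFResult, gof_summary
from .matrix import CaptureMatrix
from .specs import RDModelSpec, enumerate_model_suite


@dataclass
class DemographicSummary:
    relative_change: list[float]        # N_{t+1}/N_t per interval
    average_annual_growth: float        # percent per year
    t_years: float
    cv: float
    classification: str = ""            # set relative to the cohort mean CV


@dataclass
class SiteReport:
    site: str
    species: str
    gof: GOFResult
    c_hat: float
    criterion: str                      # "AIC" or "QAIC"
    table: pd.DataFrame                 # one row per candidate structure
    best_spec: Optional[RDModelSpec]
    best_fit: Optional[FitResult]
    abundance: Optional[pd.DataFrame]
    annual_survival: Optional[tuple[float, float, float]]  # est, lo, hi
    summary: Optional[DemographicSummary]
    log: list[str] = field(default_factory=list)


def relative_change(n_hat: Sequence[float]) -> np.ndarray:
    """Per-interval abundance ratios N_{t+1}/N_t (NaN where undefined)."""
    n = np.asarray(n_hat, dtype=float)
    if len(n) < 2:
        raise ValueError("need at least two primaries")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = n[1:] / n[:-1]
    return np.where(np.isfinite(r) & (n[:-1] > 0), r, np.nan)


def average_annual_growth(initial: float, final: float, t_years: float) -> float:
    """Average annual population growth, percent:
    ``((final / initial) ** (1 / T) - 1) * 100``."""
    if initial <= 0 or t_years <= 0 or not np.isfinite(initial) \
            or not np.isfinite(final):
        raise ValueError("need positive initial estimate and T")
    return ((final / initial) ** (1.0 / t_years) - 1.0) * 100.0


def growth_cv(ratios: Sequence[float]) -> float:
    """Coefficient of variation of the interval growth ratios (sd / mean)."""
    r = np.asarray([x for x in ratios if np.isfinite(x)], dtype=float)
    if len(r) < 2:
        raise ValueError("need at least two defined growth ratios")
    mean = r.mean()
    if mean <= 0:
        raise ValueError("mean growth ratio must be positive")
    return float(r.std(ddof=1) / mean)


def _t_years(design) -> float:
    """Elapsed years between the first and last surveyed months."""
    first, last = design.occasions[0], design.occasions[-1]
    return ((last.year - first.year) * 12 + (last.month - first.month)) / 12.0


def _annual_survival(fit: FitResult, design) -> tuple[float, float, float]:
    """Compound six-month survival (and its CI endpoints) to 12 months."""
    ci = fit.conf_int
    rows = [n for n in ci.index if n == "S" or n.startswith("S[")]
    if not rows:
        return (float("nan"),) * 3
    if len(rows) == 1:
        est, lo, hi = ci.loc[rows[0], ["estimate", "lo", "hi"]]
        return float(est) ** 2, float(lo) ** 2, float(hi) ** 2
    est = float(np.prod([ci.loc[r, "estimate"] for r in rows]))
    lo = float(np.prod([ci.loc[r, "lo"] for r in rows]))
    hi = float(np.prod([ci.loc[r, "hi"] for r in rows]))
    return est, lo, hi


def run_site_analysis(matrix: CaptureMatrix, alpha: float = 0.05,
                      group_size: int = 3,
                      specs: Sequence[RDModelSpec] | None = None,
                      **fit_options) -> SiteReport:
    """Fit the full candidate suite to one site and summarize the best model.

    Goodness-of-fit is computed once per site; ranking uses QAIC exactly
    when any component fails (otherwise AIC).  Ties break toward fewer
    parameters, then suite enumeration order.  Non-converged fits are
    excluded from the ranking and logged; if nothing converges the site is
    reported unfit rather than raising.
    """
    log: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gof = gof_summary(matrix, group_size=group_size, alpha=alpha)
    criterion = "QAIC" if gof.failed else "AIC"
    specs = list(enumerate_model_suite(matrix.design) if specs is None else specs)

    rows = []
    fits: list[Optional[FitResult]] = []
    for order, spec in enumerate(specs):
        est = RobustDesignModel(spec.survival, spec.emigration, spec.detection,
                                **fit_options)
        try:
            est.fit(matrix)
            fit = est.result_
            fit._estimator = est  # keep the fitted estimator for abundance
        except Exception as exc:  # defensive: a bad fit must not kill the site
            log.append(f"{spec.name}: fit raised {exc!r}")
            fit = None
        fits.append(fit)
        if fit is None:
            rows.append(dict(model=spec.name, n_par=np.nan, loglik=np.nan,
                             aic=np.nan, qaic=np.nan, converged=False,
                             order=order))
            continue
        aic, qaic = information_criterion(fit, gof.c_hat)
        if not fit.converged:
            log.append(f"{spec.name}: did not converge; excluded from ranking")
        rows.append(dict(model=spec.name, n_par=fit.n_par,
                         loglik=fit.log_likelihood, aic=aic, qaic=qaic,
                         converged=fit.converged, order=order))
    table = pd.DataFrame(rows)
    key = "qaic" if criterion == "QAIC" else "aic"
    ranked = table[table.converged].sort_values(
        [key, "n_par", "order"], kind="stable")
    table = table.drop(columns="order")

    if ranked.empty:
        log.append("no model converged; site reported unfit")
        return SiteReport(matrix.site, matrix.species, gof, gof.c_hat,
                          criterion, table, None, None, None, None, None, log)

    best_i = int(ranked.index[0])
    best_fit = fits[best_i]
    best_spec = specs[best_i]
    est = best_fit._estimator
    abundance = est.abundance()

    n_hat = abundance["N_hat"].to_numpy()
    t_years = _t_years(matrix.design)
    ratios = relative_change(n_hat)
    try:
        growth = average_annual_growth(n_hat[0], n_hat[-1], t_years)
    except ValueError:
        growth = float("nan")
    try:
        cv = growth_cv(ratios)
    except ValueError:
        cv = float("nan")
    summary = DemographicSummary(
        relative_change=[float(r) for r in ratios],
        average_annual_growth=growth, t_years=t_years, cv=cv)
    return SiteReport(matrix.site, matrix.species, gof, gof.c_hat, criterion,
                      table, best_spec, best_fit, abundance,
                      _annual_survival(best_fit, matrix.design), summary, log)


def classify_stability(growth_pct: float, cv: float, mean_cv: float) -> str:
    """Stability class relative to the cohort mean CV."""
    trend = "increasing" if growth_pct >= 0 else "decreasing"
    stability = "stable" if cv <= mean_cv else "unstable"
    return f"{trend}-{stability}"


# -- report bundle -----------------------------------------------------------

REPORT_SCHEMA_NAME = "site_report.schema.json"


def _summary_frame(reports: Sequence[SiteReport]) -> pd.DataFrame:
    cvs = [r.summary.cv for r in reports
           if r.summary and np.isfinite(r.summary.cv)]
    mean_cv = float(np.mean(cvs)) if cvs else float("nan")
    rows = []
    for r in reports:
        s = r.summary
        rows.append(dict(
            site=r.site, species=r.species,
            best_model=r.best_spec.name if r.best_spec else "",
            criterion=r.criterion, c_hat=r.c_hat,
            n_individuals=int(r.abundance["n"].sum()) if r.abundance is not None else 0,
            annual_survival=r.annual_survival[0] if r.annual_survival else np.nan,
            survival_lo=r.annual_survival[1] if r.annual_survival else np.nan,
            survival_hi=r.annual_survival[2] if r.annual_survival else np.nan,
            average_annual_growth_pct=s.average_annual_growth if s else np.nan,
            cv=s.cv if s else np.nan,
            classification=(classify_stability(s.average_annual_growth, s.cv,
                                               mean_cv)
                            if s and np.isfinite(s.cv)
                            and np.isfinite(s.average_annual_growth) else ""),
        ))
    return pd.DataFrame(rows)


def _clean(obj):
    """Recursively replace NaN/inf with None for strict JSON output."""
    if isinstance(obj, dict):
        return {k: _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        return float(obj) if math.isfinite(obj) else None
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def report_to_dict(report: SiteReport) -> dict:
    d = {
        "site": report.site,
        "species": report.species,
        "criterion": report.criterion,
        "c_hat": report.c_hat,
        "gof": {
            "failed": report.gof.failed,
            "chi2": report.gof.chi2_total,
            "df": report.gof.df_total,
            "components": {k: {"chi2": v.chi2, "df": v.df,
                               "p": None if math.isnan(v.p) else v.p}
                           for k, v in report.gof.components.items()},
        },
        "best_model": report.best_spec.name if report.best_spec else None,
        "model_table": report.table.to_dict(orient="records"),
        "log": report.log,
    }
    if report.abundance is not None:
        d["abundance"] = report.abundance.replace({np.nan: None}) \
            .to_dict(orient="records")
    if report.annual_survival is not None:
        est, lo, hi = report.annual_survival
        d["annual_survival"] = {"estimate": est, "lo": lo, "hi": hi}
    if report.summary is not None:
        s = report.summary
        d["summary"] = {
            "relative_change": s.relative_change,
            "average_annual_growth_pct": s.average_annual_growth,
            "t_years": s.t_years,
            "cv": s.cv,
        }
    return _clean(d)


def validate_report_dict(d: dict) -> None:
    """Check a serialized site report against the shipped JSON schema.

    A minimal structural validator (required keys and primitive types);
    raises ``ValueError`` on the first violation.
    """
    schema_path = Path(__file__).parent / "data" / REPORT_SCHEMA_NAME
    schema = json.loads(schema_path.read_text())
    _validate_node(d, schema, "$")


def _validate_node(value, schema: dict, where: str) -> None:
    t = schema.get("type")
    types = {"object": dict, "array": list, "string": str, "boolean": bool}
    if t in types and not isinstance(value, types[t]):
        raise ValueError(f"{where}: expected {t}, got {type(value).__name__}")
    if t == "number" and not (isinstance(value, (int, float))
                              and not isinstance(value, bool)):
        raise ValueError(f"{where}: expected number, got {type(value).__name__}")
    if t == "object":
        for key in schema.get("required", []):
            if key not in value:
                raise ValueError(f"{where}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in value and value[key] is not None:
                _validate_node(value[key], sub, f"{where}.{key}")
    if t == "array" and "items" in schema:
        for i, item in enumerate(value):
            if item is not None:
                _validate_node(item, schema["items"], f"{where}[{i}]")


def write_report(reports: Sequence[SiteReport], destination,
                 figures: bool = True) -> pd.DataFrame:
    """Write the report bundle: per-site JSON + tables, summary CSV, figures.

    Returns the combined summary table (one row per site x species) whose
    stability classification is taken relative to the cohort mean CV.
    """
    if not reports:
        raise ValueError("need at least one site report")
    out = Path(destination)
    out.mkdir(parents=True, exist_ok=True)
    summary = _summary_frame(reports)
    summary.to_csv(out / "summary.csv", index=False)

    for r in reports:
        stem = f"{r.site}_{r.species}".replace("/", "-")
        d = report_to_dict(r)
        validate_report_dict(d)
        (out / f"{stem}.json").write_text(
            json.dumps(d, indent=2, sort_keys=True, allow_nan=False))
        r.table.to_csv(out / f"{stem}_models.csv", index=False)
        if r.abundance is not None:
            r.abundance.to_csv(out / f"{stem}_abundance.csv", index=False)

    if figures:
        _render_figures(reports, summary, out)
    return summary


def _render_figures(reports, summary: pd.DataFrame, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 5))
    for r in reports:
        if r.abundance is None:
            continue
        a = r.abundance
        ax.errorbar(a["primary"], a["N_hat"], yerr=a["se"], marker="o",
                    capsize=3, label=f"{r.site} ({r.species})")
    ax.set_xlabel("primary period")
    ax.set_ylabel("estimated abundance")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out / "abundance_series.png", dpi=150)
    plt.close(fig)

    ok = summary[np.isfinite(summary["cv"])
                 & np.isfinite(summary["average_annual_growth_pct"])]
    fig, ax = plt.subplots(figsize=(7, 5))
    ax.scatter(ok["average_annual_growth_pct"], ok["cv"])
    for _, row in ok.iterrows():
        ax.annotate(f'{row["site"]}', (row["average_annual_growth_pct"],
                                       row["cv"]), fontsize=7)
    ax.axvline(0.0, color="red", linestyle="--", label="0% growth")
    if len(ok):
        mean_cv = ok["cv"].mean()
        ax.axhline(mean_cv, color="red", label="mean CV")
        if len(ok) > 1:
            half = stats.t.ppf(0.975, len(ok) - 1) * ok["cv"].std(ddof=1) \
                / np.sqrt(len(ok))
            ax.axhspan(mean_cv - half, mean_cv + half, color="red", alpha=0.15,
                       label="95% CI (across sites)")
    ax.set_xlabel("average annual growth (%)")
    ax.set_ylabel("CV of interval growth ratios")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out / "growth_vs_cv.png", dpi=150)
    plt.close(fig)
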