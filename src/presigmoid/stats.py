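"""Paired statistics over the cohort table.

The study design is fully paired: every procedure is performed on every
specimen, so contrasts between procedures use the paired t-test.
Contrasts of TL-R or TL-C against TL-S use a one-tailed test (any amount
of sinus retraction can only open the corridor, so the alternative is
directional); the TL-C vs TL-R contrast and the presigmoid-depth
contrasts are two-tailed.  Percent-increase summaries, Pearson
correlations with the presigmoid window, and an exact noncentral-t power
computation for paired designs complete the layer.  No multiple-testing
correction is applied; the report carries the number of tests run so
users can apply their own.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import PresigmoidError, ValidationError

__all__ = ["ComparisonResult", "CorrelationResult", "PowerConfig", "AnalysisReport",
           "paired_t", "percent_increase", "pearson", "paired_t_power",
           "required_sample_size", "analyze_cohort"]

EXPOSURE_METRICS = ("sf_total", "ea_iac", "ea_bulb", "aa")
ALL_METRICS = EXPOSURE_METRICS + ("presigmoid_depth",)
CONTRASTS = (("TL-S", "TL-R"), ("TL-S", "TL-C"), ("TL-R", "TL-C"))


@dataclass(frozen=True)
class ComparisonResult:
    """A paired contrast of one metric between two procedures
    (differences are treated - baseline)."""

    metric: str
    baseline: str
    treated: str
    n: int
    mean_diff: float
    sd_diff: float
    t_statistic: float
    p_one_tailed: float
    p_two_tailed: float
    pct_increase_mean: float
    pct_increase_sd: float
    pct_increase_min: float
    pct_increase_max: float
    preferred_tails: int
    degenerate: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    x: str
    y: str
    n: int
    r: float
    p_two_tailed: float


@dataclass(frozen=True)
class PowerConfig:
    """Power / sample-size assumptions for a paired design.

    detectable_effect_fraction: smallest relative exposure change worth
        detecting (0.15 = 15 %).
    assumed_cv: coefficient of variation of the paired differences
        (relative SD); the standardized effect is
        detectable_effect_fraction / assumed_cv.
    """

    alpha: float = 0.05
    power: float = 0.9
    detectable_effect_fraction: float = 0.15
    assumed_cv: float = 0.12
    tails: int = 2

    def __post_init__(self):
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise PresigmoidError("alpha and power must be in (0, 1)")
        if self.detectable_effect_fraction <= 0 or self.assumed_cv <= 0:
            raise PresigmoidError("effect fraction and assumed_cv must be > 0")
        if self.tails not in (1, 2):
            raise PresigmoidError("tails must be 1 or 2")


def paired_t(a, b, tails: int = 2, metric: str = "", baseline: str = "",
             treated: str = "") -> ComparisonResult:
    """Paired t-test of matched samples; the one-tailed p tests b > a.

    t = mean(d) / (sd(d)/sqrt(n)) with d = b - a and the sample SD
    (n-1 denominator); p-values come from the t distribution with n-1
    degrees of freedom.  With all differences zero the test is reported
    as t = 0, p2 = 1; zero spread around a nonzero mean sets the
    degenerate flag (infinite t).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise PresigmoidError("paired_t needs two equal-length 1D samples")
    n = a.size
    if n < 2:
        raise PresigmoidError("paired_t needs n >= 2")
    if tails not in (1, 2):
        raise PresigmoidError("tails must be 1 or 2")
    d = b - a
    mean_d = float(np.mean(d))
    sd_d = float(np.std(d, ddof=1))
    degenerate = False
    if sd_d == 0.0:
        if mean_d == 0.0:
            t = 0.0
            p2 = 1.0
        else:
            degenerate = True
            t = np.inf if mean_d > 0 else -np.inf
            p2 = 0.0
    else:
        t = mean_d / (sd_d / np.sqrt(n))
        p2 = float(2.0 * sps.t.sf(abs(t), n - 1))
    p1 = float(sps.t.sf(t, n - 1)) if np.isfinite(t) else (0.0 if t > 0 else 1.0)
    if np.all(a > 0):
        pct = percent_increase(a, b)
    else:
        pct = {"mean": np.nan, "sd": np.nan, "min": np.nan, "max": np.nan}
    return ComparisonResult(
        metric=metric, baseline=baseline, treated=treated, n=n,
        mean_diff=mean_d, sd_diff=sd_d, t_statistic=float(t),
        p_one_tailed=p1, p_two_tailed=p2,
        pct_increase_mean=pct["mean"], pct_increase_sd=pct["sd"],
        pct_increase_min=pct["min"], pct_increase_max=pct["max"],
        preferred_tails=tails, degenerate=degenerate,
    )


def percent_increase(baseline, treated) -> dict:
    """Per-specimen percent change 100*(treated-baseline)/baseline,
    summarized as mean / sample SD / range."""
    baseline = np.asarray(baseline, dtype=float)
    treated = np.asarray(treated, dtype=float)
    if baseline.shape != treated.shape:
        raise PresigmoidError("percent_increase needs matched samples")
    if np.any(baseline <= 0):
        raise PresigmoidError("percent_increase: baseline values must be > 0")
    pct = 100.0 * (treated - baseline) / baseline
    sd = float(np.std(pct, ddof=1)) if pct.size > 1 else 0.0
    return {"mean": float(np.mean(pct)), "sd": sd,
            "min": float(np.min(pct)), "max": float(np.max(pct))}


def pearson(x, y, x_name: str = "x", y_name: str = "y") -> CorrelationResult:
    """Product-moment correlation with the two-tailed t-transform p
    (n-2 degrees of freedom)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise PresigmoidError("pearson needs two equal-length samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise PresigmoidError("pearson is undefined for a constant input")
    n = x.size
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(t, n - 2))
    return CorrelationResult(x=x_name, y=y_name, n=n, r=r, p_two_tailed=p)


def paired_t_power(n: int, standardized_effect: float, alpha: float = 0.05,
                   tails: int = 2) -> float:
    """Exact power of the paired t-test at sample size n for a
    standardized effect (mean difference / SD of differences), via the
    noncentral t distribution."""
    if n < 2:
        return 0.0
    df = n - 1
    ncp = standardized_effect * np.sqrt(n)
    if tails == 2:
        tc = sps.t.ppf(1.0 - alpha / 2.0, df)
        return float(sps.nct.sf(tc, df, ncp) + sps.nct.cdf(-tc, df, ncp))
    tc = sps.t.ppf(1.0 - alpha, df)
    return float(sps.nct.sf(tc, df, ncp))


def required_sample_size(cfg: PowerConfig, n_max: int = 10_000) -> int:
    """Smallest n whose exact paired-t power reaches cfg.power for the
    standardized effect detectable_effect_fraction / assumed_cv."""
    effect = cfg.detectable_effect_fraction / cfg.assumed_cv
    for n in range(2, n_max + 1):
        if paired_t_power(n, effect, cfg.alpha, cfg.tails) >= cfg.power:
            return n
    raise PresigmoidError(f"required sample size exceeds {n_max}")


# ---------------------------------------------------------------------------
# the full analysis battery
# ---------------------------------------------------------------------------

@dataclass
class AnalysisReport:
    """All paired contrasts and correlations over one cohort table."""

    comparisons: pd.DataFrame
    correlations: pd.DataFrame
    n_tests: int
    excluded_specimens: list = field(default_factory=list)

    def to_csv(self, path) -> None:
        """One CSV with a `section` column separating the two batteries."""
        comp = self.comparisons.copy()
        comp.insert(0, "section", "comparison")
        corr = self.correlations.copy()
        corr.insert(0, "section", "correlation")
        pd.concat([comp, corr], ignore_index=True).to_csv(path, index=False)

    def summary(self) -> str:
        lines = [f"paired contrasts: {len(self.comparisons)}, "
                 f"correlations: {len(self.correlations)}, "
                 f"tests run (no multiplicity correction): {self.n_tests}"]
        if self.excluded_specimens:
            lines.append(f"excluded specimens (incomplete): {self.excluded_specimens}")
        for _, row in self.comparisons.iterrows():
            tail = "p1" if row.preferred_tails == 1 else "p2"
            p = row.p_one_tailed if row.preferred_tails == 1 else row.p_two_tailed
            lines.append(
                f"{row.metric:17s} {row.treated} vs {row.baseline}: "
                f"diff {row.mean_diff:+8.2f} +/- {row.sd_diff:6.2f} "
                f"({tail} = {p:.4f}, mean increase {row.pct_increase_mean:+.1f}%)")
        return "\n".join(lines)


def _tails_for(metric: str, baseline: str) -> int:
    if metric in EXPOSURE_METRICS and baseline == "TL-S":
        return 1
    return 2


def analyze_cohort(table: pd.DataFrame) -> AnalysisReport:
    """The full statistical battery over a cohort table.

    Specimens missing any procedure are excluded with a warning (mirroring
    incomplete-dissection exclusions).  For every metric and every
    procedure contrast a paired comparison (absolute difference and
    percent increase) is reported; the correlation battery relates the
    presigmoid window (area and depth at TL-S) to SF, to the SF percent
    increases, and to each angular measure under every procedure.
    """
    required = {"TL-S", "TL-R", "TL-C"}
    by_spec = table.groupby("specimen_id")["procedure"].agg(set)
    excluded = sorted(by_spec.index[by_spec.apply(lambda s: not required <= s)])
    if excluded:
        warnings.warn(f"excluding specimens with missing procedures: {excluded}",
                      stacklevel=2)
    kept = table[~table["specimen_id"].isin(excluded)]
    if kept.empty:
        raise ValidationError("no complete specimens to analyze")
    wide = {proc: kept[kept["procedure"] == proc]
            .set_index("specimen_id").sort_index() for proc in required}
    n_spec = len(wide["TL-S"])
    if any(len(w) != n_spec for w in wide.values()):
        raise ValidationError("duplicate procedure rows for a specimen")

    comparisons = []
    for metric in ALL_METRICS:
        for baseline, treated in CONTRASTS:
            tails = _tails_for(metric, baseline)
            comparisons.append(paired_t(
                wide[baseline][metric].to_numpy(), wide[treated][metric].to_numpy(),
                tails=tails, metric=metric, baseline=baseline, treated=treated))
    comp_df = pd.DataFrame([asdict(c) for c in comparisons])

    def _corr(x, y, xn, yn):
        try:
            return pearson(x, y, xn, yn)
        except PresigmoidError:
            # constant input (e.g. a zero-effect cohort): undefined r
            return CorrelationResult(x=xn, y=yn, n=len(x), r=np.nan,
                                     p_two_tailed=np.nan)

    correlations = []
    base = wide["TL-S"]
    predictors = {"presigmoid_area": base["presigmoid_area"].to_numpy(),
                  "presigmoid_depth": base["presigmoid_depth"].to_numpy()}
    for pname, pvals in predictors.items():
        correlations.append(_corr(pvals, base["sf_total"].to_numpy(),
                                  pname, "sf_total@TL-S"))
        for treated in ("TL-R", "TL-C"):
            pct = 100.0 * (wide[treated]["sf_total"].to_numpy()
                           - base["sf_total"].to_numpy()) / base["sf_total"].to_numpy()
            correlations.append(_corr(pvals, pct, pname,
                                      f"sf_pct_increase@{treated}"))
        for metric in ("ea_iac", "ea_bulb", "aa"):
            for proc in ("TL-S", "TL-R", "TL-C"):
                correlations.append(_corr(pvals, wide[proc][metric].to_numpy(),
                                          pname, f"{metric}@{proc}"))
    corr_df = pd.DataFrame([asdict(c) for c in correlations])

    return AnalysisReport(comparisons=comp_df, correlations=corr_df,
                          n_tests=len(comp_df) + len(corr_df),
                          excluded_specimens=excluded)
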