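"""Reverse-rating response analysis.

The analysis asks which motion cues (horizontal amplitude, vertical
amplitude, velocity) drive the high/low contrast of each social category.
Final slider settings are the predictors in a logistic regression with the
item polarity as binomial outcome (high = 1, low = 0).  Because the three
cues are substantially inter-correlated, coefficient interpretation leans
on three complementary views:

* multi-predictor logistic fits with profile-likelihood 95% CIs,
* single-predictor fits (immune to multicollinearity by construction),
* Johnson relative importance weights: regress the outcome on the best
  orthogonal approximation Z of the standardized predictor matrix X
  (via the SVD X = P D Q', Z = P Q'), then fold the squared surrogate
  coefficients back through the squared loadings L = Q D Q'.  The weights
  are nonnegative, unaffected by multicollinearity, and sum to the model's
  explained variance — exactly R^2 in the linear case, a pseudo-R^2 analog
  (squared correlation between outcome and fitted probability, by default)
  in the logistic case.

Significance is Bonferroni-controlled over the experiment's family of 30
tests (5 categories x 3 predictors x 2 model families), and differences
between estimates are read off CI overlap: intervals that touch or are
disjoint correspond to roughly p < .01 (Cumming & Finch guideline).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import brentq
from scipy.stats import chi2

PREDICTORS = ("s_h", "s_v", "s_vel")
DEFAULT_FAMILY_SIZE = 30  # 5 categories x 3 predictors x 2 model families


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation: the MLE does not exist."""


class RankError(ValueError):
    """Constant or collinear predictors make the design rank-deficient."""


# ---------------------------------------------------------------------------
# Descriptives
# ---------------------------------------------------------------------------

def descriptives(records: pd.DataFrame, predictors=PREDICTORS) -> pd.DataFrame:
    """Median and quartiles of each slider per (category, polarity).

    Quantiles use linear interpolation between order statistics.  Empty
    groups are omitted with a warning.
    """
    if records.empty:
        raise ValueError("response table is empty")
    rows = []
    for (category, polarity), group in records.groupby(
        ["category", "polarity"], sort=True
    ):
        if group.empty:  # pragma: no cover - groupby drops empty groups
            warnings.warn(f"empty group ({category}, {polarity}) omitted")
            continue
        for comp in predictors:
            q1, med, q3 = group[comp].quantile([0.25, 0.5, 0.75], interpolation="linear")
            rows.append(
                {
                    "category": category,
                    "polarity": int(polarity),
                    "component": comp,
                    "median": float(med),
                    "q1": float(q1),
                    "q3": float(q3),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Logistic regression with profile-likelihood CIs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogisticFit:
    """A fitted polarity ~ sliders logistic regression for one category."""

    category: str
    predictors: tuple[str, ...]
    estimates: dict
    std_errors: dict
    conf_int: dict  # predictor -> (lower, upper), 95%
    p_values: dict  # two-sided Wald
    n: int
    intercept: float
    ci_method: str = "profile"  # profile | wald
    log_likelihood: float = float("nan")


def _category_design(records: pd.DataFrame, category: str, predictors) -> tuple:
    sub = records[records["category"] == category]
    if sub.empty:
        raise ValueError(f"no records for category {category!r}")
    y = sub["polarity"].to_numpy(dtype=float)
    if np.unique(y).size < 2:
        raise ValueError(f"category {category!r} lacks one polarity")
    X = sub[list(predictors)].to_numpy(dtype=float)
    for j, name in enumerate(predictors):
        if np.unique(X[:, j]).size < 2:
            raise RankError(f"predictor {name!r} is constant for category {category!r}")
    return X, y


def _fit_logit(y: np.ndarray, exog: np.ndarray):
    """Logit MLE with explicit separation detection."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # promote separation warnings
            res = sm.Logit(y, exog).fit(disp=0, maxiter=200)
    except Exception as exc:  # PerfectSeparation*, convergence, singular
        if "eparation" in type(exc).__name__ or "eparation" in str(exc):
            raise SeparationError(
                "complete or quasi-complete separation: a hyperplane splits the "
                "high and low responses perfectly; the logistic MLE does not "
                "exist. Inspect the raw sliders or pool more data."
            ) from exc
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, exog).fit(disp=0, maxiter=200, method="bfgs")
    if (not res.mle_retvals.get("converged", True)) or np.abs(res.params).max() > 30:
        raise SeparationError(
            "logistic fit diverged (unbounded coefficients), indicating "
            "complete or quasi-complete separation"
        )
    return res


def _profile_ci(y, exog, j, res, alpha=0.05):
    """Profile-likelihood CI for coefficient j of a fitted Logit.

    Solves 2*(llf_max - profile_llf(b)) = chi2_{1,1-alpha} on each side of
    the MLE via offset refits and Brent root finding.
    """
    target = res.llf - 0.5 * chi2.ppf(1 - alpha, df=1)
    beta, se = res.params[j], res.bse[j]
    others = np.delete(exog, j, axis=1)
    xj = exog[:, j]

    def deficit(b: float) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prof = sm.GLM(y, others, family=sm.families.Binomial(), offset=b * xj).fit(
                maxiter=200
            )
        return prof.llf - target

    bounds = []
    for direction in (-1.0, 1.0):
        step = 1.0
        lo_b = beta
        hi_b = None
        for _ in range(30):
            cand = beta + direction * step * se
            if deficit(cand) < 0:
                hi_b = cand
                break
            lo_b = cand
            step *= 1.8
        if hi_b is None:
            raise RuntimeError("profile likelihood bound not bracketed")
        bounds.append(brentq(deficit, min(lo_b, hi_b), max(lo_b, hi_b), xtol=1e-8))
    lower, upper = sorted(bounds)
    return lower, upper


def fit_logistic(
    records: pd.DataFrame,
    category: str,
    predictors=PREDICTORS,
    ci_method: str = "profile",
) -> LogisticFit:
    """Maximum-likelihood logistic regression of polarity on slider values.

    95% CIs come from the profile likelihood (falling back to Wald with a
    warning if profiling fails); p-values are two-sided Wald.  Separation
    raises :class:`SeparationError` rather than returning a divergent fit.
    """
    predictors = tuple(predictors)
    X, y = _category_design(records, category, predictors)
    exog = sm.add_constant(X, has_constant="add")
    res = _fit_logit(y, exog)

    conf = {}
    used_method = ci_method
    if ci_method == "profile":
        try:
            for j, name in enumerate(predictors, start=1):
                conf[name] = _profile_ci(y, exog, j, res)
        except RuntimeError:
            warnings.warn("profile likelihood CI failed; falling back to Wald")
            used_method = "wald"
    if used_method != "profile":
        wald = res.conf_int()
        conf = {name: (float(wald[j][0]), float(wald[j][1]))
                for j, name in enumerate(predictors, start=1)}

    return LogisticFit(
        category=category,
        predictors=predictors,
        estimates={n: float(res.params[j]) for j, n in enumerate(predictors, 1)},
        std_errors={n: float(res.bse[j]) for j, n in enumerate(predictors, 1)},
        conf_int={n: (float(lo), float(hi)) for n, (lo, hi) in conf.items()},
        p_values={n: float(res.pvalues[j]) for j, n in enumerate(predictors, 1)},
        n=len(y),
        intercept=float(res.params[0]),
        ci_method=used_method,
        log_likelihood=float(res.llf),
    )


# ---------------------------------------------------------------------------
# Johnson relative importance weights
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RelativeWeightsResult:
    """Per-predictor relative weights and the explained-variance total."""

    predictors: tuple[str, ...]
    weights: dict  # predictor -> epsilon_j >= 0
    total_r2: float  # sum of weights
    r2_name: str  # "R2" (linear) or the pseudo-R2 analog used

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if any(w < -1e-12 for w in self.weights.values()):
            raise ValueError("relative weights must be nonnegative")
        if abs(total - self.total_r2) > 1e-6:
            raise ValueError("weights must sum to the model's explained variance")


def _pseudo_r2(y: np.ndarray, fitted: np.ndarray, res, kind: str) -> float:
    if kind == "corr":
        return float(np.corrcoef(y, fitted)[0, 1] ** 2)
    if kind == "mcfadden":
        return float(1.0 - res.llf / res.llnull)
    raise ValueError(f"unknown pseudo-R2 analog {kind!r}")


def johnson_relative_weights(
    X: np.ndarray,
    y: np.ndarray,
    binary: bool | None = None,
    pseudo_r2: str = "corr",
) -> tuple[np.ndarray, float]:
    """Relative weights of the columns of X for outcome y.

    Returns ``(epsilon, total)`` where ``epsilon[j] >= 0`` and
    ``epsilon.sum() == total``, the model's explained variance (OLS R^2
    for a continuous outcome; the chosen pseudo-R^2 analog for a binary
    one).  Invariant to predictor order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need more observations than predictors")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise RankError("zero-variance predictor column")
    Xs = (X - X.mean(axis=0)) / sd
    if np.linalg.matrix_rank(Xs) < p:
        raise RankError("predictor matrix is rank-deficient")
    if binary is None:
        binary = set(np.unique(y)) <= {0.0, 1.0}

    U, d, Vt = np.linalg.svd(Xs, full_matrices=False)
    Z = U @ Vt  # best orthogonal approximation of Xs (Z'Z = I)
    lam = (Vt.T * d) @ Vt / np.sqrt(n - 1)  # lam[j,k] = corr(x_j, z_k)
    lam_sq = lam**2

    if binary:
        # scale surrogate columns to unit variance so coefficient magnitudes
        # are comparable across n; the rescale to the pseudo-R2 total below
        # absorbs the constant factor
        exog = sm.add_constant(Z * np.sqrt(n - 1), has_constant="add")
        res = _fit_logit(y, exog)
        beta = res.params[1:]
        raw = lam_sq @ beta**2
        total = _pseudo_r2(y, res.predict(exog), res, pseudo_r2)
        eps = raw * (total / raw.sum()) if raw.sum() > 0 else raw
        return eps, float(total)

    ys = (y - y.mean()) / y.std(ddof=1)
    beta_star = Z.T @ ys / np.sqrt(n - 1)  # = corr(z_k, y)
    eps = lam_sq @ beta_star**2
    return eps, float(eps.sum())


def relative_weights(
    records: pd.DataFrame,
    category: str,
    predictors=PREDICTORS,
    pseudo_r2: str = "corr",
) -> RelativeWeightsResult:
    """Johnson relative weights of the three sliders for one category."""
    predictors = tuple(predictors)
    X, y = _category_design(records, category, predictors)
    eps, total = johnson_relative_weights(X, y, binary=True, pseudo_r2=pseudo_r2)
    return RelativeWeightsResult(
        predictors=predictors,
        weights={name: float(w) for name, w in zip(predictors, eps)},
        total_r2=total,
        r2_name=f"pseudo-R2 ({pseudo_r2})",
    )


# ---------------------------------------------------------------------------
# Diagnostics and inference helpers
# ---------------------------------------------------------------------------

def predictor_correlations(
    records: pd.DataFrame, category: str, predictors=PREDICTORS
) -> pd.DataFrame:
    """Pearson correlations among the sliders over one category's records."""
    sub = records[records["category"] == category]
    if sub.empty:
        raise ValueError(f"no records for category {category!r}")
    cols = sub[list(predictors)]
    if (cols.std(ddof=1) == 0).any():
        warnings.warn("zero-variance predictor: undefined correlation entries (NaN)")
    return cols.corr(method="pearson")


def bonferroni_family(pvalues, m: int = DEFAULT_FAMILY_SIZE, alpha: float = 0.05):
    """Bonferroni control over a family of m tests.

    Returns ``(flags, adjusted_alpha)`` where ``flags[i]`` is True when
    ``pvalues[i] < alpha / m``.
    """
    pvalues = list(pvalues)
    if m <= 0:
        raise ValueError("family size must be positive")
    if m < len(pvalues):
        raise ValueError(
            f"family size {m} smaller than the {len(pvalues)} tests considered jointly"
        )
    adjusted = alpha / m
    return [bool(p < adjusted) for p in pvalues], adjusted


@dataclass(frozen=True)
class OverlapVerdict:
    """Interval-arithmetic comparison of two 95% CIs."""

    relation: str  # disjoint_or_touching | overlapping
    interpretation: str


def ci_overlap(ci_a, ci_b) -> OverlapVerdict:
    """Cumming & Finch reading of two 95% CIs.

    Intervals that are disjoint or touch at a single point correspond to
    roughly p < .01; anything else supports no difference claim.
    """
    (a_lo, a_hi), (b_lo, b_hi) = ci_a, ci_b
    if a_lo > a_hi or b_lo > b_hi:
        raise ValueError("confidence interval bounds are inverted")
    if a_hi <= b_lo or b_hi <= a_lo:
        return OverlapVerdict(
            relation="disjoint_or_touching",
            interpretation="difference, p < .01 equivalent (Cumming & Finch guideline)",
        )
    return OverlapVerdict(relation="overlapping", interpretation="overlapping — no claim")


# ---------------------------------------------------------------------------
# Report building
# ---------------------------------------------------------------------------

def build_report(
    records: pd.DataFrame,
    experiment: str,
    family_size: int = DEFAULT_FAMILY_SIZE,
    predictors=PREDICTORS,
    pseudo_r2: str = "corr",
) -> dict:
    """Full analysis report for one experiment.

    Emits (a) a descriptives table, (b) a multi-predictor regression table
    with estimates, SEs, profile CIs, relative weights and the R^2 column
    (which equals the summed weights row-wise by construction), and (c) a
    single-predictor table.  Categories missing either polarity are
    omitted with a warning.  All values are plain Python scalars so the
    report serializes to JSON deterministically.
    """
    predictors = tuple(predictors)
    sub = records[records["experiment"] == experiment]
    if sub.empty:
        raise ValueError(f"no records for experiment {experiment!r}")
    categories = list(dict.fromkeys(sub["category"]))

    desc = descriptives(sub, predictors).to_dict(orient="records")
    multi_rows, single_rows = [], []
    pvalues, cells = [], []  # cells[i] is the dict that owns pvalues[i]
    for category in categories:
        try:
            fit = fit_logistic(sub, category, predictors)
            rw = relative_weights(sub, category, predictors, pseudo_r2)
        except (ValueError, SeparationError) as exc:
            warnings.warn(f"multi-predictor model for {category!r} omitted: {exc}")
        else:
            row = {
                "category": category, "n": fit.n,
                "r2": rw.total_r2, "ci_method": fit.ci_method,
            }
            for name in predictors:
                row[name] = {
                    "estimate": fit.estimates[name],
                    "se": fit.std_errors[name],
                    "ci": list(fit.conf_int[name]),
                    "p": fit.p_values[name],
                    "weight": rw.weights[name],
                }
                pvalues.append(fit.p_values[name])
                cells.append(row[name])
            multi_rows.append(row)

        srow = {"category": category}
        for name in predictors:
            try:
                sfit = fit_logistic(sub, category, (name,))
            except (ValueError, SeparationError) as exc:
                warnings.warn(f"single-predictor {name} model for {category!r} omitted: {exc}")
                continue
            srow[name] = {
                "estimate": sfit.estimates[name],
                "se": sfit.std_errors[name],
                "ci": list(sfit.conf_int[name]),
                "p": sfit.p_values[name],
            }
            pvalues.append(sfit.p_values[name])
            cells.append(srow[name])
        if len(srow) > 1:
            single_rows.append(srow)

    flags, adjusted_alpha = bonferroni_family(pvalues, m=max(family_size, len(pvalues)))
    for cell, flag in zip(cells, flags):
        cell["significant"] = flag

    return {
        "experiment": experiment,
        "n_records": int(len(sub)),
        "family_size": int(max(family_size, len(pvalues))),
        "adjusted_alpha": adjusted_alpha,
        "r2_name": f"pseudo-R2 ({pseudo_r2})",
        "descriptives": desc,
        "multi_predictor": multi_rows,
        "single_predictor": single_rows,
    }


def format_report(report: dict, predictors=PREDICTORS) -> str:
    """Aligned text rendering of a report (descriptives + both regressions)."""
    lines = [f"Experiment: {report['experiment']}  (n records = {report['n_records']})", ""]
    lines.append("Descriptives: median (Q1; Q3) per item version")
    header = f"{'category':<14}{'polarity':<10}" + "".join(f"{p:>16}" for p in predictors)
    lines.append(header)
    desc = {}
    for row in report["descriptives"]:
        desc.setdefault((row["category"], row["polarity"]), {})[row["component"]] = row
    for (category, polarity), comps in desc.items():
        cells = "".join(
            f"{comps[p]['median']:.1f} ({comps[p]['q1']:.1f};{comps[p]['q3']:.1f})".rjust(16)
            for p in predictors
        )
        lines.append(f"{category:<14}{('high' if polarity else 'low'):<10}{cells}")

    lines += ["", "Multi-predictor logistic regressions "
                  "(estimate (SE) [CI]; relative weight; R2)"]
    for row in report["multi_predictor"]:
        lines.append(f"{row['category']}  R2 = {row['r2']:.2f}")
        for name in predictors:
            c = row[name]
            star = " *" if c["significant"] else ""
            lines.append(
                f"  {name:<6} {c['estimate']:+.2f} ({c['se']:.2f}) "
                f"[{c['ci'][0]:.2f}, {c['ci'][1]:.2f}]  w = {c['weight']:.2f}{star}"
            )
    lines += ["", "Single-predictor logistic regressions (estimate (SE) [CI])"]
    for row in report["single_predictor"]:
        lines.append(row["category"])
        for name in predictors:
            if name not in row:
                continue
            c = row[name]
            star = " *" if c["significant"] else ""
            lines.append(
                f"  {name:<6} {c['estimate']:+.2f} ({c['se']:.2f}) "
                f"[{c['ci'][0]:.2f}, {c['ci'][1]:.2f}]{star}"
            )
    lines.append("")
    lines.append(f"Bonferroni family: {report['family_size']} tests, "
                 f"adjusted alpha = {report['adjusted_alpha']:.7f}")
    return "\n".join(lines)
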