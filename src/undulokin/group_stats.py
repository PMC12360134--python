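"""Cross-speed statistics for per-trial kinematic summaries.

For each kinematic variable the workflow is:

1. assumption gate — Levene's test (median-centred) for homogeneity of
   variances across speed groups and Shapiro-Wilk on the residuals of the
   additive speed + individual fit; if neither rejects at alpha = 0.05 the
   parametric repeated-measures ANOVA is used, otherwise the aligned-rank-
   transform (ART) ANOVA;
2. the chosen ANOVA — an additive fixed-effect model with individuals as
   blocks (y ~ speed + individual, no interaction), sequential sums of
   squares on the possibly unbalanced table; the speed F-statistic carries
   df = (k - 1, N - 1 - (k - 1) - (n - 1));
3. all pairwise speed contrasts with Tukey-Kramer adjustment (studentized
   range on model-based contrast standard errors), summarized as a compact
   letter display (insert-and-absorb algorithm);
4. a PCA on the independent kinematic variables with per-axis percent
   variance and percent contribution of each variable.

The ART ANOVA aligns the response for the speed effect (residual from the
full additive fit plus the estimated speed effect), ranks with average ties,
and runs the same blocked ANOVA on the ranks, following the standard
aligned-rank-transform procedure for factorial designs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import studentized_range

from .errors import InsufficientDataError, ValidationError

__all__ = [
    "AnovaResult", "GateResult", "StatsReport", "PCAResult",
    "assumption_gate", "rm_anova", "art_anova", "tukey_contrasts",
    "compact_letters", "tukey_letters", "pca_contributions",
    "analyze_variable", "analyze_table", "summary_table",
    "PCA_DEFAULT_VARIABLES",
]

ALPHA = 0.05

#: the independent kinematic variables entering the PCA by default
#: (derived quantities — wavelength, fin effort, Strouhal — are excluded).
PCA_DEFAULT_VARIABLES = ("angle_of_attack", "body_angle", "amplitude",
                         "k_max", "k_max_loc", "reynolds", "tbf", "wave_speed")


# ---------------------------------------------------------------------------
# design handling
# ---------------------------------------------------------------------------

def _prepare(table: pd.DataFrame, variable: str
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list, list]:
    """Extract (y, individual codes, speed codes) for one variable.

    Drops rows with a missing response, then individuals observed at fewer
    than 2 speeds (with a warning). Duplicate (individual, speed) cells are
    a design violation.
    """
    df = table[["individual_id", "speed_bl", variable]].dropna()
    if df.duplicated(["individual_id", "speed_bl"]).any():
        raise ValidationError("table: duplicate (individual, speed) cells")
    counts = df.groupby("individual_id")["speed_bl"].nunique()
    thin = counts[counts < 2].index
    if len(thin):
        warnings.warn(f"dropping individuals with <2 speeds: {list(thin)}")
        df = df[~df["individual_id"].isin(thin)]
    inds = sorted(df["individual_id"].unique())
    speeds = sorted(df["speed_bl"].unique())
    if len(inds) < 2 or len(speeds) < 2:
        raise InsufficientDataError(
            f"{variable}: need >=2 individuals and >=2 speeds with data")
    y = df[variable].to_numpy(dtype=float)
    icode = df["individual_id"].map({v: i for i, v in enumerate(inds)}).to_numpy()
    scode = df["speed_bl"].map({v: i for i, v in enumerate(speeds)}).to_numpy()
    return y, icode, scode, inds, speeds


def _dummies(codes: np.ndarray, k: int) -> np.ndarray:
    """Treatment-coded dummy columns for levels 1..k-1 (level 0 reference)."""
    return (codes[:, None] == np.arange(1, k)[None, :]).astype(float)


def _rss(y: np.ndarray, X: np.ndarray) -> tuple[float, np.ndarray]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), beta


@dataclass
class AnovaResult:
    """Speed-effect F-test from the blocked additive model, plus everything
    the Tukey post hoc needs (coefficients, covariance, residual scale)."""

    variable: str
    method: str                  # "RM-ANOVA" or "ART-ANOVA"
    F: float
    df_num: int
    df_den: int
    p: float
    speeds: list = field(default_factory=list)
    speed_effects: np.ndarray | None = None   # k-1 coefficients vs speeds[0]
    cov_speed: np.ndarray | None = None       # their covariance
    mse: float = np.nan
    group_n: np.ndarray | None = None


def _blocked_anova(y, icode, scode, inds, speeds, variable, method) -> AnovaResult:
    n_i, n_s, N = len(inds), len(speeds), y.size
    ones = np.ones((N, 1))
    Xi = _dummies(icode, n_i)
    Xs = _dummies(scode, n_s)
    X0 = np.hstack([ones, Xi])
    X1 = np.hstack([ones, Xi, Xs])
    sse0, _ = _rss(y, X0)
    sse1, beta1 = _rss(y, X1)
    df_num = n_s - 1
    df_den = N - 1 - (n_s - 1) - (n_i - 1)
    if df_den <= 0:
        raise InsufficientDataError(f"{variable}: no residual degrees of freedom")
    tol = 1e-9 * (float(y @ y) + 1.0)
    mse = sse1 / df_den
    if sse1 <= tol:
        # saturated (or constant) response: no residual variation
        F = np.inf if sse0 - sse1 > tol else 0.0
        p = 0.0 if np.isinf(F) else 1.0
        mse = 0.0
    else:
        F = max(((sse0 - sse1) / df_num) / mse, 0.0)
        p = float(sps.f.sf(F, df_num, df_den))
    # covariance of the speed coefficients for post-hoc contrasts
    xtx_inv = np.linalg.pinv(X1.T @ X1)
    sl = slice(1 + (n_i - 1), 1 + (n_i - 1) + (n_s - 1))
    cov = mse * xtx_inv[sl, sl]
    group_n = np.bincount(scode, minlength=n_s)
    return AnovaResult(variable=variable, method=method, F=float(F),
                       df_num=df_num, df_den=df_den, p=p, speeds=list(speeds),
                       speed_effects=beta1[sl], cov_speed=cov, mse=mse,
                       group_n=group_n)


def rm_anova(table: pd.DataFrame, variable: str) -> AnovaResult:
    """Repeated-measures ANOVA for the speed effect.

    Additive two-factor least-squares fit (speed + individual) on the
    unbalanced table; F compares the individual-only model with the full
    model (sequential sums of squares). The reference design (5 individuals,
    11 speeds, 4 missing cells, 51 trials) gives df = (10, 36).
    """
    y, icode, scode, inds, speeds = _prepare(table, variable)
    return _blocked_anova(y, icode, scode, inds, speeds, variable, "RM-ANOVA")


def art_anova(table: pd.DataFrame, variable: str) -> AnovaResult:
    """Aligned-rank-transform ANOVA for the speed effect.

    Aligns the response for speed (full-model residual plus estimated speed
    effect), ranks with average ties, then applies the blocked ANOVA to the
    ranks. Invariant under strictly monotone transforms of the response.
    """
    y, icode, scode, inds, speeds = _prepare(table, variable)
    n_i, n_s, N = len(inds), len(speeds), y.size
    X1 = np.hstack([np.ones((N, 1)), _dummies(icode, n_i), _dummies(scode, n_s)])
    _, beta = _rss(y, X1)
    resid = y - X1 @ beta
    speed_part = _dummies(scode, n_s) @ beta[1 + (n_i - 1):]
    aligned = resid + speed_part
    # floating-point dust from the fit must not break ties apart
    scale = max(float(np.ptp(y)), 1.0)
    if np.ptp(aligned) <= 1e-9 * scale:
        aligned = np.zeros_like(aligned)
    ranks = sps.rankdata(aligned)
    return _blocked_anova(ranks, icode, scode, inds, speeds, variable,
                          "ART-ANOVA")


# ---------------------------------------------------------------------------
# assumption gate
# ---------------------------------------------------------------------------

@dataclass
class GateResult:
    variable: str
    levene_p: float
    shapiro_p: float
    chosen: str          # "RM-ANOVA" or "ART-ANOVA"


def assumption_gate(table: pd.DataFrame, variable: str,
                    alpha: float = ALPHA) -> GateResult:
    """Choose between the parametric and aligned-rank ANOVA.

    Levene (median-centred) across speed groups on the raw values and
    Shapiro-Wilk on the additive-model residuals; both must fail to reject
    at ``alpha`` for the parametric test. Constant data (either test
    undefined) falls back to ART with a warning.
    """
    y, icode, scode, inds, speeds = _prepare(table, variable)
    groups = [y[scode == j] for j in range(len(speeds))]
    X1 = np.hstack([np.ones((y.size, 1)), _dummies(icode, len(inds)),
                    _dummies(scode, len(speeds))])
    _, beta = _rss(y, X1)
    resid = y - X1 @ beta
    if np.ptp(y) == 0 or np.ptp(resid) < 1e-12 * max(np.ptp(y), 1.0):
        warnings.warn(f"{variable}: (near-)constant data; "
                      "normality test undefined, falling back to ART-ANOVA")
        return GateResult(variable, np.nan, np.nan, "ART-ANOVA")
    levene_p = float(sps.levene(*groups, center="median").pvalue)
    shapiro_p = float(sps.shapiro(resid).pvalue)
    chosen = "RM-ANOVA" if (levene_p > alpha and shapiro_p > alpha) else "ART-ANOVA"
    return GateResult(variable, levene_p, shapiro_p, chosen)


# ---------------------------------------------------------------------------
# Tukey contrasts and compact letter display
# ---------------------------------------------------------------------------

def tukey_contrasts(result: AnovaResult) -> pd.DataFrame:
    """All pairwise speed contrasts with Tukey-Kramer adjusted p-values.

    Contrast estimates and standard errors come from the fitted additive
    model (so they are adjusted for the individual blocks and for unequal
    group sizes); p = P(q_{k, df} >= |estimate| * sqrt(2) / SE).
    """
    k = len(result.speeds)
    eff = np.concatenate([[0.0], result.speed_effects])
    cov = np.zeros((k, k))
    cov[1:, 1:] = result.cov_speed
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            if result.group_n is not None and (
                    result.group_n[i] < 2 and result.group_n[j] < 2):
                warnings.warn(f"contrast {result.speeds[i]} vs "
                              f"{result.speeds[j]}: singleton groups; skipped")
                continue
            est = eff[j] - eff[i]
            var = cov[i, i] + cov[j, j] - 2 * cov[i, j]
            if var <= 0:
                p = 0.0 if est != 0 else 1.0
            else:
                q = abs(est) * np.sqrt(2.0 / var)
                p = float(studentized_range.sf(q, k, result.df_den))
            rows.append({"speed_a": result.speeds[i], "speed_b": result.speeds[j],
                         "estimate": est, "se": np.sqrt(max(var, 0.0)),
                         "p_tukey": p})
    return pd.DataFrame(rows)


def compact_letters(levels: list, sig_pairs: set[tuple]) -> dict:
    """Compact letter display via insert-and-absorb.

    ``sig_pairs`` holds the significantly different pairs. Two levels share
    a letter iff they are not significantly different. Letters are assigned
    in the given level order.
    """
    sets: list[set] = [set(levels)]
    for a, b in sorted(sig_pairs, key=lambda p: (levels.index(p[0]),
                                                 levels.index(p[1]))):
        new = []
        for s in sets:
            if a in s and b in s:
                new.extend([s - {a}, s - {b}])
            else:
                new.append(s)
        # absorb: drop any set contained in another
        new = [s for s in new if s]
        sets = [s for i, s in enumerate(new)
                if not any(i != j and s < o or (s == o and i > j)
                           for j, o in enumerate(new))]
    sets.sort(key=lambda s: min(levels.index(x) for x in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lv: "" for lv in levels}
    for letter, s in zip(alphabet, sets):
        for lv in s:
            out[lv] += letter
    return {lv: ",".join(out[lv]) for lv in levels}


def tukey_letters(result: AnovaResult, alpha: float = ALPHA
                  ) -> tuple[pd.DataFrame, dict]:
    """Pairwise Tukey table plus the per-speed letter groups."""
    contrasts = tukey_contrasts(result)
    sig = {(r.speed_a, r.speed_b) for r in contrasts.itertuples()
           if r.p_tukey <= alpha}
    letters = compact_letters(result.speeds, sig)
    return contrasts, letters


# ---------------------------------------------------------------------------
# PCA with contributions
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    variables: list
    scores: np.ndarray            # (n_rows, n_axes)
    loadings: np.ndarray          # (n_vars, n_axes), unit eigenvectors
    percent_variance: np.ndarray  # per axis, sums to 100
    contributions: np.ndarray     # (n_vars, n_axes) percent, each axis sums to 100
    row_index: pd.Index | None = None
    dropped_rows: list = field(default_factory=list)


def pca_contributions(table: pd.DataFrame,
                      variables: tuple[str, ...] = PCA_DEFAULT_VARIABLES,
                      orient_by: str | np.ndarray | None = "speed_bl"
                      ) -> PCAResult:
    """PCA on z-scored variables with per-axis variable contributions.

    Rows with any missing variable are dropped (and listed). The
    contribution of variable j to axis k is 100 * loading(j,k)^2 /
    sum_j loading(j,k)^2. Each axis is oriented so its scores correlate
    positively with ``orient_by`` (a column name or vector) when that
    correlation is nonzero; orientation changes signs only, never variances
    or contributions.
    """
    if len(variables) < 2:
        raise InsufficientDataError("need >= 2 variables for a PCA")
    sub = table[list(variables)]
    complete = sub.notna().all(axis=1)
    dropped = list(table.index[~complete])
    X = sub[complete].to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise InsufficientDataError("need >= 3 complete rows for a PCA")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        const = [v for v, s in zip(variables, sd) if s == 0]
        raise ValidationError(f"constant variable(s): {const}")
    Z = (X - X.mean(axis=0)) / sd
    # SVD of the standardized matrix == eigendecomposition of the
    # correlation matrix
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    var = S ** 2
    percent = 100.0 * var / var.sum()
    scores = U * S
    loadings = Vt.T
    if orient_by is not None:
        ref = (table.loc[sub[complete].index, orient_by].to_numpy(dtype=float)
               if isinstance(orient_by, str) else np.asarray(orient_by)[complete])
        for k in range(scores.shape[1]):
            r = np.corrcoef(scores[:, k], ref)[0, 1]
            if np.isfinite(r) and r < 0:
                scores[:, k] *= -1
                loadings[:, k] *= -1
    contrib = 100.0 * loadings ** 2 / (loadings ** 2).sum(axis=0, keepdims=True)
    return PCAResult(variables=list(variables), scores=scores,
                     loadings=loadings, percent_variance=percent,
                     contributions=contrib,
                     row_index=sub[complete].index, dropped_rows=dropped)


# ---------------------------------------------------------------------------
# per-variable driver and report
# ---------------------------------------------------------------------------

@dataclass
class StatsReport:
    """Per-variable test choice and result, plus per-speed summaries."""

    tests: pd.DataFrame           # variable, levene_p, shapiro_p, method, F, df, p
    letters: pd.DataFrame         # variable x speed letter groups
    contrasts: dict               # variable -> pairwise Tukey DataFrame
    alpha: float = ALPHA


def analyze_variable(table: pd.DataFrame, variable: str,
                     alpha: float = ALPHA
                     ) -> tuple[GateResult, AnovaResult, pd.DataFrame, dict]:
    gate = assumption_gate(table, variable, alpha=alpha)
    fit = (rm_anova if gate.chosen == "RM-ANOVA" else art_anova)(table, variable)
    contrasts, letters = tukey_letters(fit, alpha=alpha)
    return gate, fit, contrasts, letters


def analyze_table(table: pd.DataFrame, variables: list[str],
                  alpha: float = ALPHA) -> StatsReport:
    """Run the gate + ANOVA + Tukey letters for every variable."""
    test_rows, letter_rows, contrast_map = [], [], {}
    for v in variables:
        gate, fit, contrasts, letters = analyze_variable(table, v, alpha=alpha)
        test_rows.append({"variable": v, "levene_p": gate.levene_p,
                          "shapiro_p": gate.shapiro_p, "method": fit.method,
                          "F": fit.F, "df_num": fit.df_num,
                          "df_den": fit.df_den, "p": fit.p})
        for spd, let in letters.items():
            letter_rows.append({"variable": v, "speed_bl": spd, "letters": let})
        contrast_map[v] = contrasts
    return StatsReport(tests=pd.DataFrame(test_rows),
                       letters=pd.DataFrame(letter_rows),
                       contrasts=contrast_map, alpha=alpha)


def summary_table(table: pd.DataFrame,
                  variables: tuple[str, ...] = ("tbf", "wave_speed",
                                                "fin_effort", "body_angle"),
                  alpha: float = ALPHA) -> pd.DataFrame:
    """Per-speed mean +/- SD with Tukey letter groups, one block per
    variable (the cross-speed kinematics table)."""
    report = analyze_table(table, list(variables), alpha=alpha)
    rows = []
    for v in variables:
        g = table.groupby("speed_bl")[v]
        letters = report.letters.query("variable == @v") \
                                .set_index("speed_bl")["letters"]
        for spd in sorted(table["speed_bl"].unique()):
            rows.append({"variable": v, "speed_bl": spd,
                         "mean": g.mean().get(spd, np.nan),
                         "sd": g.std(ddof=1).get(spd, np.nan),
                         "n": int(g.count().get(spd, 0)),
                         "letters": letters.get(spd, "")})
    return pd.DataFrame(rows)
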