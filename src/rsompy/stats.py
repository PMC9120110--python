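"""Cohort statistics: Mann-Whitney U, logistic combination, ROC/AUC.

Group differences between nevi and melanomas are tested per biomarker with
the two-tailed Mann-Whitney U test (exact null distribution for small
untied samples, normal approximation with tie and continuity corrections
otherwise).  Single-marker discrimination is summarized by the empirical
ROC and its trapezoidal AUC; marker combinations are scored by in-sample
predicted probabilities of a maximum-likelihood logistic regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit

from .datatypes import BIOMARKER_COLUMNS

__all__ = [
    "mann_whitney_u",
    "fit_logistic",
    "roc_auc",
    "cohort_report",
    "StatsReport",
    "MARKER_ORIENTATION",
]

# direction in which each biomarker points toward melanoma: +1 means higher
# values indicate malignancy, -1 lower (vessels around melanoma are shorter)
MARKER_ORIENTATION: dict[str, int] = {
    "tbv": +1,
    "vessel_density": +1,
    "avg_vessel_length_um": -1,
    "tortuosity": +1,
    "fractal_number": +1,
    "lacunarity": +1,
}


def mann_whitney_u(
    group_a: np.ndarray,
    group_b: np.ndarray,
    exact_max_n: int = 16,
) -> dict[str, float]:
    """Two-tailed Mann-Whitney U test.

    ``U`` is the statistic of ``group_a`` (number of (a, b) pairs with
    a > b, counting ties as 1/2).  The exact permutation null is used when
    the combined sample size is at most ``exact_max_n`` and there are no
    ties; otherwise the normal approximation with tie correction and
    continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    if a.size + b.size <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return {"U": float(res.statistic), "p": float(min(res.pvalue, 1.0)),
            "method": method}


@dataclass
class LogisticFit:
    coef: np.ndarray
    intercept: float
    converged: bool
    separation: bool
    n_iter: int

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        eta = self.intercept + np.asarray(X, dtype=float) @ self.coef
        return expit(eta)


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
    ridge_on_separation: float = 1e-4,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by IRLS, intercept included.

    Perfect separation is detected as a diverging coefficient norm (or a
    singular working system); the fit then restarts with a small ridge
    penalty so finite coefficients are returned, and the flag is set.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y size mismatch")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("labels contain a single class")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")

    Xd = np.column_stack([np.ones(X.shape[0]), X])
    n, p = Xd.shape

    def _irls(ridge: float) -> tuple[np.ndarray, bool, bool, int]:
        beta = np.zeros(p)
        separation = False
        for it in range(1, max_iter + 1):
            eta = Xd @ beta
            mu = expit(eta)
            w = mu * (1.0 - mu)
            H = Xd.T @ (w[:, None] * Xd) + ridge * np.eye(p)
            g = Xd.T @ (y - mu) - ridge * beta
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                separation = True
                break
            beta = beta + step
            if np.linalg.norm(beta) > 1e3:
                separation = True
                break
            if np.max(np.abs(step)) < tol:
                return beta, True, False, it
        return beta, False, separation, max_iter

    beta, converged, separation, n_iter = _irls(0.0)
    if separation:
        beta, converged, _, n_iter = _irls(ridge_on_separation)
        separation = True
    return LogisticFit(
        coef=beta[1:], intercept=float(beta[0]), converged=converged,
        separation=separation, n_iter=n_iter,
    )


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> dict:
    """Empirical ROC curve and trapezoidal AUC.

    ``labels`` are boolean/0-1 with 1 = positive class.  Ties in scores are
    traversed jointly, producing the diagonal segments whose trapezoidal
    area equals the Mann-Whitney statistic U / (n_pos * n_neg).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # cumulative counts at each distinct threshold
    distinct = np.nonzero(np.diff(s_sorted))[0]
    idx = np.concatenate([distinct, [s.size - 1]])
    tps = np.cumsum(y_sorted)[idx]
    fps = np.cumsum(~y_sorted)[idx]
    tpr = np.concatenate([[0.0], tps / n_pos])
    fpr = np.concatenate([[0.0], fps / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return {"fpr": fpr, "tpr": tpr, "auc": auc}


@dataclass
class StatsReport:
    """Per-marker group statistics plus single-marker and combined ROC."""

    markers: dict[str, dict] = field(default_factory=dict)
    combined: dict = field(default_factory=dict)
    groups: tuple[str, str] = ("nevus", "melanoma")
    n_per_group: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def _clean(d):
            out = {}
            for k, v in d.items():
                if isinstance(v, np.ndarray):
                    out[k] = v.tolist()
                elif isinstance(v, dict):
                    out[k] = _clean(v)
                elif isinstance(v, (np.floating, np.integer)):
                    out[k] = v.item()
                else:
                    out[k] = v
            return out

        return {
            "groups": list(self.groups),
            "n_per_group": dict(self.n_per_group),
            "markers": _clean(self.markers),
            "combined": _clean(self.combined),
        }


# published group summary statistics (mean, SD) for the six biomarkers at
# the lesion edge; nevus group first, melanoma second.  tbv is a fraction.
REFERENCE_COHORT_SUMMARY: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "tbv": ((0.2362, 0.0561), (0.3594, 0.0622)),
    "vessel_density": ((0.010, 0.0035), (0.017, 0.004)),
    "avg_vessel_length_um": ((260.39, 62.49), (139.60, 46.63)),
    "tortuosity": ((0.27, 0.082), (0.47, 0.083)),
    "fractal_number": ((1.12, 0.062), (1.26, 0.18)),
    "lacunarity": ((0.088, 0.050), (0.170, 0.083)),
}


def make_synthetic_cohort(
    summary: dict | None = None,
    n_per_group: int = 16,
    region: str = "edge",
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic stand-in cohort table matched to published group summaries.

    Per-lesion biomarker values are not redistributable, so this draws
    normal deviates per group and affinely rescales them to reproduce the
    published group means and sample SDs exactly.  Group means/SDs of the
    output are therefore faithful; the correlation structure between
    markers (and hence multivariate statistics) is synthetic.
    """
    if summary is None:
        summary = REFERENCE_COHORT_SUMMARY
    rng = np.random.default_rng(seed)
    rows = []
    for gi, group in enumerate(("nevus", "melanoma")):
        data = {}
        for marker, stats_pair in summary.items():
            mean, sd = stats_pair[gi]
            x = rng.standard_normal(n_per_group)
            x = (x - x.mean()) / x.std(ddof=1)
            data[marker] = mean + sd * x
        for i in range(n_per_group):
            rows.append(
                {
                    "lesion_id": f"{group[0].upper()}{i + 1:02d}",
                    "group": group,
                    "region": region,
                    **{m: data[m][i] for m in summary},
                }
            )
    return pd.DataFrame(rows)


def cohort_report(
    table: pd.DataFrame,
    markers: list[str] | None = None,
    combine: tuple[str, ...] = ("tbv", "tortuosity"),
) -> StatsReport:
    """Full cohort comparison between the nevus and melanoma groups.

    Per marker: group means and sample SDs (ddof=1), the Mann-Whitney U
    of the melanoma group and its two-tailed p, and the ROC AUC with the
    melanoma-pointing orientation fixed a priori (higher values indicate
    melanoma for every marker except average vessel length, where shorter
    vessels do).  The combined model scores samples by in-sample predicted
    probabilities of a logistic regression on standardized features.
    """
    if markers is None:
        markers = list(BIOMARKER_COLUMNS)
    groups = table["group"].unique().tolist()
    for g in ("nevus", "melanoma"):
        if g not in groups:
            raise ValueError(f"group {g!r} missing from the cohort table")
    nevus = table[table["group"] == "nevus"]
    melanoma = table[table["group"] == "melanoma"]
    labels = (table["group"] == "melanoma").to_numpy()

    report = StatsReport(
        n_per_group={"nevus": len(nevus), "melanoma": len(melanoma)}
    )
    for m in markers:
        mw = mann_whitney_u(melanoma[m].to_numpy(), nevus[m].to_numpy())
        orientation = MARKER_ORIENTATION.get(m, +1)
        roc = roc_auc(orientation * table[m].to_numpy(), labels)
        report.markers[m] = {
            "mean_nevus": float(nevus[m].mean()),
            "sd_nevus": float(nevus[m].std(ddof=1)),
            "mean_melanoma": float(melanoma[m].mean()),
            "sd_melanoma": float(melanoma[m].std(ddof=1)),
            "U": mw["U"],
            "p": mw["p"],
            "p_method": mw["method"],
            "auc": roc["auc"],
            "orientation": orientation,
        }
    if combine:
        X = table[list(combine)].to_numpy(dtype=float)
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xs = (X - mu) / sd
        fit = fit_logistic(Xs, labels.astype(float))
        proba = fit.predict_proba(Xs)
        roc = roc_auc(proba, labels)
        report.combined = {
            "markers": list(combine),
            "coef": fit.coef,
            "intercept": fit.intercept,
            "separation": fit.separation,
            "auc": roc["auc"],
        }
    return report
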