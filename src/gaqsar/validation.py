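"""Internal/external validation statistics, Y-scrambling and applicability domain.

The battery follows the conventional QSAR validation canon:

* fitting: R2, adjusted R2, F, RMSE/MAE, residual standard error;
* internal: Q2_LOO (closed-form PRESS), Q2_LMO over random left-out groups;
* external: Q2_F1 / Q2_F2 / Q2_F3, Lin's concordance correlation coefficient,
  and the through-origin r2m family (r2o, r'2o, slopes k and k', average and
  delta of r2m in both regression directions);
* chance correlation: Y-scrambling (refit on permuted responses) and the
  multivariate K correlation indices Kxx / delta K;
* applicability domain: Williams plot quantities — leverage against
  standardized residuals with warning leverage h* = 3(p+1)/n.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import json
import numpy as np
import pandas as pd

from .model_search import MLRModel, fit_mlr, hat_diagonal, press_loo, q2_loo

__all__ = [
    "ValidationReport",
    "internal_stats",
    "q2_lmo",
    "external_stats",
    "ccc",
    "rm2_metrics",
    "k_indices",
    "y_scramble",
    "williams_domain",
    "validate_model",
    "check_thresholds",
    "DEFAULT_THRESHOLDS",
    "plot_predicted_vs_observed",
    "plot_williams",
]


@dataclass
class ValidationReport:
    """The full statistic battery; pKi-unit fields are RMSE/MAE/s_y."""

    r2: float = np.nan
    r2_adj: float = np.nan
    r2_ex: float = np.nan
    q2_loo: float = np.nan
    q2_lmo: float = np.nan
    rmse_tr: float = np.nan
    rmse_cv: float = np.nan
    rmse_ex: float = np.nan
    mae_tr: float = np.nan
    mae_cv: float = np.nan
    mae_ex: float = np.nan
    s_y: float = np.nan
    f_stat: float = np.nan
    ccc_tr: float = np.nan
    ccc_cv: float = np.nan
    ccc_ex: float = np.nan
    q2_f1: float = np.nan
    q2_f2: float = np.nan
    q2_f3: float = np.nan
    rm2_avg: float = np.nan
    rm2_delta: float = np.nan
    k_slope: float = np.nan
    k_slope_prime: float = np.nan
    r2o: float = np.nan
    r2o_prime: float = np.nan
    kxx: float = np.nan
    delta_k: float = np.nan
    r2_yscr: float = np.nan
    q2_yscr: float = np.nan
    rss_tr: float = np.nan
    press_cv: float = np.nan
    press_ex: float = np.nan

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_csv_row(self) -> pd.DataFrame:
        return pd.DataFrame([self.to_dict()])


# The conventional acceptance cutoffs for a predictive QSAR model:
# R2tr >= 0.6, Q2loo >= 0.5, Q2LMO >= 0.6, R2ex >= 0.6, CCC >= 0.80,
# Q2-Fn >= 0.60, r2m >= 0.5, delta K >= 0.05, slopes k/k' in [0.9, 1.1];
# plus the derived conditions handled in check_thresholds: R2 > Q2,
# RMSEtr < RMSEcv, |r2o - r'2o| < 0.3 and the Golbraikh-Tropsha
# through-origin ratio test.
DEFAULT_THRESHOLDS: dict[str, tuple[str, float]] = {
    "r2": (">=", 0.6),
    "q2_loo": (">=", 0.5),
    "q2_lmo": (">=", 0.6),
    "r2_ex": (">=", 0.6),
    "ccc_tr": (">=", 0.80),
    "q2_f1": (">=", 0.60),
    "q2_f2": (">=", 0.60),
    "q2_f3": (">=", 0.60),
    "rm2_avg": (">=", 0.5),
    "delta_k": (">=", 0.05),
    "k_slope": ("in", (0.9, 1.1)),
    "k_slope_prime": ("in", (0.9, 1.1)),
}


def check_thresholds(
    report: ValidationReport,
    thresholds: dict[str, tuple[str, object]] | None = None,
) -> dict[str, bool]:
    """Evaluate threshold flags, including the derived pass/fail conditions
    (R2 > Q2, PRESS inflation, through-origin agreement)."""
    thresholds = thresholds if thresholds is not None else DEFAULT_THRESHOLDS
    flags: dict[str, bool] = {}
    values = report.to_dict()
    for key, (op, ref) in thresholds.items():
        v = values[key]
        if not np.isfinite(v):
            flags[key] = False
        elif op == ">=":
            flags[key] = bool(v >= ref)
        elif op == "<=":
            flags[key] = bool(v <= ref)
        elif op == "in":
            lo, hi = ref
            flags[key] = bool(lo <= v <= hi)
        else:
            raise ValueError(f"unknown comparison {op!r}")
    def fin(*keys):
        return all(np.isfinite(values[k]) for k in keys)

    if fin("rmse_tr", "rmse_cv"):
        flags["rmse_tr_lt_cv"] = bool(values["rmse_tr"] < values["rmse_cv"])
    if fin("r2", "q2_loo"):
        flags["r2_gt_q2"] = bool(values["r2"] > values["q2_loo"])
    if fin("r2o", "r2o_prime"):
        flags["r2o_gap_lt_0p3"] = bool(
            abs(values["r2o"] - values["r2o_prime"]) < 0.3
        )
    if fin("r2_ex", "r2o", "r2o_prime", "k_slope", "k_slope_prime"):
        r2e = values["r2_ex"]
        direct = (values["r2o"] != 0 and (1 - r2e / values["r2o"]) < 0.1
                  and 0.9 <= values["k_slope"] <= 1.1)
        primed = (values["r2o_prime"] != 0 and (1 - r2e / values["r2o_prime"]) < 0.1
                  and 0.9 <= values["k_slope_prime"] <= 1.1)
        flags["golbraikh_tropsha"] = bool(direct or primed)
    return flags


def internal_stats(model: MLRModel, X_tr: pd.DataFrame | np.ndarray,
                   y_tr: np.ndarray) -> dict[str, float]:
    """Fitting statistics of the trained model on its own training data."""
    y_tr = np.asarray(y_tr, dtype=float)
    yhat = model.predict(X_tr)
    n = len(y_tr)
    p = len(model.coefficients)
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    resid = y_tr - yhat
    rss = float(resid @ resid)
    tss = float(np.sum((y_tr - y_tr.mean()) ** 2))
    ess = tss - rss
    r2 = 1.0 - rss / tss
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    f_stat = (ess / p) / (rss / (n - p - 1))
    s_y = float(np.sqrt(rss / (n - p - 1)))
    Xnum = X_tr.to_numpy(dtype=float) if isinstance(X_tr, pd.DataFrame) else np.asarray(X_tr, float)
    press = press_loo(Xnum, y_tr)
    h = hat_diagonal(Xnum)
    loo_pred = y_tr - resid / (1.0 - h)
    return {
        "r2": r2,
        "r2_adj": r2_adj,
        "f_stat": f_stat,
        "rmse_tr": float(np.sqrt(rss / n)),
        "mae_tr": float(np.mean(np.abs(resid))),
        "s_y": s_y,
        "rss_tr": rss,
        "q2_loo": 1.0 - press / tss,
        "press_cv": press,
        "rmse_cv": float(np.sqrt(press / n)),
        "mae_cv": float(np.mean(np.abs(y_tr - loo_pred))),
        "ccc_tr": ccc(y_tr, yhat),
        "ccc_cv": ccc(y_tr, loo_pred),
    }


def q2_lmo(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    leave_out_fraction: float = 0.3,
    n_iterations: int = 1000,
    seed: int = 0,
) -> float:
    """Leave-many-out cross-validation: mean of 1 - PRESS/TSS over random groups.

    Each iteration leaves out ``leave_out_fraction`` of the points, refits on
    the remainder, and scores the held-out predictions against the held-out
    TSS about the training-subset mean.
    """
    if not 0.0 < leave_out_fraction <= 0.5:
        raise ValueError("leave_out_fraction must be in (0, 0.5]")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    n_out = int(round(leave_out_fraction * n))
    if n_out < 1:
        raise ValueError("left-out group is empty at this fraction")
    if n - n_out <= p + 1:
        raise ValueError("too few points remain to fit after leaving the group out")
    rng = np.random.default_rng(seed)
    vals = np.empty(n_iterations)
    for it in range(n_iterations):
        out = rng.choice(n, size=n_out, replace=False)
        mask = np.ones(n, dtype=bool)
        mask[out] = False
        model = fit_mlr(X[mask], y[mask])
        pred = model.predict(X[~mask])
        press = float(np.sum((y[~mask] - pred) ** 2))
        tss = float(np.sum((y[~mask] - y[mask].mean()) ** 2))
        vals[it] = 1.0 - press / tss
    return float(vals.mean())


def ccc(y: np.ndarray, yhat: np.ndarray) -> float:
    """Lin's concordance correlation coefficient (population moments)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    vy, vp = y.var(), yhat.var()
    if vy == 0 or vp == 0:
        raise ValueError("zero-variance vector in CCC")
    cov = np.mean((y - y.mean()) * (yhat - yhat.mean()))
    return float(2.0 * cov / (vy + vp + (y.mean() - yhat.mean()) ** 2))


def _through_origin(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope k of y ~ k x through the origin and the associated r2o
    (1 - residual SS about the origin line / TSS about the mean of y)."""
    k = float(x @ y / (x @ x))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2o = 1.0 - float(np.sum((y - k * x) ** 2)) / tss
    return k, r2o


def rm2_metrics(y_obs: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    """Roy's r2m family from through-origin regressions in both directions.

    With r2 the squared Pearson correlation,
    ``rm2 = r2 * (1 - sqrt(r2 - r2o))`` for observed-vs-predicted and the
    primed variant for predicted-vs-observed; reported as average and
    absolute difference.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.var() == 0 or y_pred.var() == 0:
        raise ValueError("zero-variance vector in r2m metrics")
    r = np.corrcoef(y_obs, y_pred)[0, 1]
    r2 = float(r * r)
    k_slope, r2o = _through_origin(y_pred, y_obs)       # obs on pred axis
    k_prime, r2o_prime = _through_origin(y_obs, y_pred)  # pred on obs axis
    rm2 = r2 * (1.0 - np.sqrt(max(r2 - r2o, 0.0)))
    rm2_prime = r2 * (1.0 - np.sqrt(max(r2 - r2o_prime, 0.0)))
    return {
        "k_slope": k_slope,
        "k_slope_prime": k_prime,
        "r2o": r2o,
        "r2o_prime": r2o_prime,
        "rm2_avg": float((rm2 + rm2_prime) / 2.0),
        "rm2_delta": float(abs(rm2 - rm2_prime)),
    }


def external_stats(
    model: MLRModel,
    X_ex: pd.DataFrame | np.ndarray,
    y_ex: np.ndarray,
    y_tr: np.ndarray,
) -> dict[str, float]:
    """External predictivity: Q2_F1/F2/F3, CCC and the r2m family.

    Q2_F1 references the training mean, Q2_F2 the external mean, and Q2_F3
    compares per-observation mean squared errors against the training
    variance (n_tr denominator).
    """
    y_ex = np.asarray(y_ex, dtype=float)
    y_tr = np.asarray(y_tr, dtype=float)
    if len(y_ex) == 0:
        raise ValueError("external set is empty")
    yhat = model.predict(X_ex)
    press_ex = float(np.sum((yhat - y_ex) ** 2))
    n_ex, n_tr = len(y_ex), len(y_tr)
    ss_tr_mean = float(np.sum((y_ex - y_tr.mean()) ** 2))
    ss_ex_mean = float(np.sum((y_ex - y_ex.mean()) ** 2))
    tss_tr = float(np.sum((y_tr - y_tr.mean()) ** 2))
    out = {
        "q2_f1": 1.0 - press_ex / ss_tr_mean,
        "q2_f2": 1.0 - press_ex / ss_ex_mean,
        "q2_f3": 1.0 - (press_ex / n_ex) / (tss_tr / n_tr),
        "press_ex": press_ex,
        "rmse_ex": float(np.sqrt(press_ex / n_ex)),
        "mae_ex": float(np.mean(np.abs(y_ex - yhat))),
        "ccc_ex": ccc(y_ex, yhat),
        "r2_ex": float(np.corrcoef(y_ex, yhat)[0, 1] ** 2),
    }
    out.update(rm2_metrics(y_ex, yhat))
    return out


def _k_index(block: np.ndarray) -> float:
    """Todeschini's multivariate K correlation index of a variable block."""
    corr = np.corrcoef(block, rowvar=False)
    if not np.all(np.isfinite(corr)):
        raise ValueError("non-finite correlation (constant column?) in K index")
    m = corr.shape[0]
    lam = np.linalg.eigvalsh(corr)
    lam = np.clip(lam, 0.0, None)
    frac = lam / lam.sum()
    return float(np.sum(np.abs(frac - 1.0 / m)) / (2.0 * (m - 1) / m))


def k_indices(X: pd.DataFrame | np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(Kxx, delta K): correlation structure of the descriptors alone and the
    gain when the response joins the block. delta K >= 0.05 suggests the
    response genuinely correlates with the descriptor block."""
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least two descriptors for K indices")
    kxx = _k_index(X)
    kxy = _k_index(np.column_stack([X, np.asarray(y, dtype=float)]))
    return kxx, kxy - kxx


def y_scramble(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    n_scrambles: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Chance-correlation baseline: refit on permuted responses.

    Returns the mean R2 and mean Q2_LOO over the scrambled refits on the
    fixed descriptor subset. A real model should sit far above both means.
    """
    if n_scrambles < 1:
        raise ValueError("n_scrambles must be >= 1")
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    A = np.column_stack([np.ones(len(X)), X])
    q, _ = np.linalg.qr(A)
    h = np.einsum("ij,ij->i", q, q)
    r2s = np.empty(n_scrambles)
    q2s = np.empty(n_scrambles)
    for i in range(n_scrambles):
        yp = rng.permutation(y)
        # project once per permutation; same design throughout
        yhat = q @ (q.T @ yp)
        resid = yp - yhat
        rss = float(resid @ resid)
        tss = float(np.sum((yp - yp.mean()) ** 2))
        r2s[i] = 1.0 - rss / tss
        press = float(np.sum((resid / (1.0 - h)) ** 2))
        q2s[i] = 1.0 - press / tss
    return float(r2s.mean()), float(q2s.mean())


def williams_domain(
    model: MLRModel,
    X_tr: pd.DataFrame | np.ndarray,
    X_query: pd.DataFrame | np.ndarray,
    y_tr: np.ndarray,
    y_query: np.ndarray | None = None,
    leverage_factor: float = 3.0,
    residual_cutoff: float = 3.0,
) -> pd.DataFrame:
    """Williams-plot quantities for query points.

    Leverage is ``h = a (A'A)^-1 a'`` with the intercept-augmented training
    design; the warning leverage is ``h* = 3 (p+1) / n``. Standardized
    residuals (observed queries only) use the training residual standard
    error; a point is in-domain when ``h <= h*`` and, where observed,
    ``|standardized residual| <= 3``.
    """
    names = model.descriptor_names
    if isinstance(X_tr, pd.DataFrame):
        X_tr = X_tr[names].to_numpy(dtype=float)
    if isinstance(X_query, pd.DataFrame):
        ids = list(X_query.index)
        X_query = X_query[names].to_numpy(dtype=float)
    else:
        X_query = np.asarray(X_query, dtype=float)
        ids = list(range(len(X_query)))
    X_tr = np.asarray(X_tr, dtype=float)
    y_tr = np.asarray(y_tr, dtype=float)
    n, p = X_tr.shape
    A = np.column_stack([np.ones(n), X_tr])
    xtx = A.T @ A
    if np.linalg.matrix_rank(xtx) < p + 1:
        raise np.linalg.LinAlgError("singular X'X in leverage computation")
    xtx_inv = np.linalg.inv(xtx)
    Aq = np.column_stack([np.ones(len(X_query)), X_query])
    leverage = np.einsum("ij,jk,ik->i", Aq, xtx_inv, Aq)
    h_star = leverage_factor * (p + 1) / n
    resid_tr = y_tr - model.predict(X_tr)
    s = float(np.sqrt(resid_tr @ resid_tr / (n - p - 1)))
    if y_query is not None:
        std_resid = (np.asarray(y_query, dtype=float) - model.predict(X_query)) / s
        in_domain = (leverage <= h_star) & (np.abs(std_resid) <= residual_cutoff)
    else:
        std_resid = np.full(len(X_query), np.nan)
        in_domain = leverage <= h_star
    out = pd.DataFrame(
        {
            "leverage": leverage,
            "std_residual": std_resid,
            "in_domain": in_domain,
        },
        index=pd.Index(ids, name="compound_id"),
    )
    out.attrs["h_star"] = h_star
    return out


def validate_model(
    model: MLRModel,
    X_tr: pd.DataFrame,
    y_tr: np.ndarray,
    X_ex: pd.DataFrame | None = None,
    y_ex: np.ndarray | None = None,
    lmo_fraction: float = 0.3,
    lmo_iterations: int = 1000,
    n_scrambles: int = 1000,
    seed: int = 0,
) -> ValidationReport:
    """Assemble the full :class:`ValidationReport` for a fitted model."""
    report = ValidationReport()
    stats = internal_stats(model, X_tr, y_tr)
    Xnum = X_tr[model.descriptor_names]
    stats["q2_lmo"] = q2_lmo(Xnum, y_tr, lmo_fraction, lmo_iterations, seed=seed)
    kxx, dk = k_indices(Xnum, y_tr)
    stats["kxx"], stats["delta_k"] = kxx, dk
    r2_scr, q2_scr = y_scramble(Xnum, y_tr, n_scrambles=n_scrambles, seed=seed + 1)
    stats["r2_yscr"], stats["q2_yscr"] = r2_scr, q2_scr
    if X_ex is not None and y_ex is not None and len(y_ex):
        stats.update(external_stats(model, X_ex, y_ex, y_tr))
    for key, val in stats.items():
        if key in report.__dataclass_fields__:
            setattr(report, key, float(val))
    return report


# ---------------------------------------------------------------------------
# plots (SVG; mirrors the usual predicted-vs-observed and Williams figures)


def plot_predicted_vs_observed(y_obs, y_pred, path, split_labels=None):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    if split_labels is None:
        ax.scatter(y_obs, y_pred, s=18, alpha=0.8)
    else:
        for lab in sorted(set(split_labels)):
            mask = np.asarray([sl == lab for sl in split_labels])
            ax.scatter(np.asarray(y_obs)[mask], np.asarray(y_pred)[mask],
                       s=18, alpha=0.8, label=lab)
        ax.legend()
    lims = [min(np.min(y_obs), np.min(y_pred)), max(np.max(y_obs), np.max(y_pred))]
    ax.plot(lims, lims, "k--", lw=1)
    ax.set_xlabel("observed pKi")
    ax.set_ylabel("predicted pKi")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_williams(domain_df: pd.DataFrame, path, residual_cutoff: float = 3.0):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    ax.scatter(domain_df["leverage"], domain_df["std_residual"], s=18, alpha=0.8)
    h_star = domain_df.attrs.get("h_star")
    if h_star is not None:
        ax.axvline(h_star, color="r", ls="--", lw=1, label=f"h* = {h_star:.3f}")
    ax.axhline(residual_cutoff, color="k", ls=":", lw=1)
    ax.axhline(-residual_cutoff, color="k", ls=":", lw=1)
    ax.set_xlabel("leverage")
    ax.set_ylabel("standardized residual")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
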