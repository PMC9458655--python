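"""Two-sample summary-statistic Mendelian randomization estimators.

Instruments are rows of (beta_exposure, se_exposure, beta_outcome,
se_outcome); the outcome scale is assumed to be log-odds, and report helpers
exponentiate to odds ratios.  Estimators: inverse-variance weighted (fixed
effect, with multiplicative random-effects inflation when Cochran's
Q/(n-1) > 1), MR-Egger weighted regression with intercept, simple and
weighted median with seeded parametric-bootstrap standard errors, and the
joint-normal maximum-likelihood estimator that profiles out the true
per-variant exposure effects.

Pleiotropy screening follows a leave-one-out Q-contribution scheme: each
variant's squared residual from the IVW fit of the remaining variants is
referred to chi-square(1), and Benjamini-Hochberg at FDR 0.2 flags variants
for removal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import minimize_scalar

REQUIRED_COLUMNS = ("beta_exposure", "se_exposure", "beta_outcome", "se_outcome")


@dataclass
class MrResult:
    method: str
    estimate: float
    se: float
    p_value: float
    n_instruments: int
    model: str = "fixed"  # fixed | random (IVW inflation applied)
    intercept: float | None = None
    se_intercept: float | None = None
    p_intercept: float | None = None

    @property
    def ci(self) -> tuple[float, float]:
        return self.estimate - 1.959964 * self.se, self.estimate + 1.959964 * self.se

    def odds_ratio_row(self) -> dict:
        lo, hi = self.ci
        return {
            "method": self.method,
            "or": math.exp(self.estimate),
            "or_lo": math.exp(lo),
            "or_hi": math.exp(hi),
            "p_value": self.p_value,
        }


def _extract(instruments: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    for col in REQUIRED_COLUMNS:
        if col not in instruments.columns:
            raise ValueError(f"instrument table missing column {col!r}")
    bx = instruments["beta_exposure"].to_numpy(dtype=float)
    sx = instruments["se_exposure"].to_numpy(dtype=float)
    by = instruments["beta_outcome"].to_numpy(dtype=float)
    sy = instruments["se_outcome"].to_numpy(dtype=float)
    if np.any(sx <= 0) or np.any(sy <= 0):
        raise ValueError("standard errors must be positive")
    return bx, sx, by, sy


def _orient_positive(bx: np.ndarray, by: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip instruments so every exposure effect is nonnegative (the usual
    Egger identifiability convention)."""
    sign = np.where(bx < 0, -1.0, 1.0)
    return bx * sign, by * sign


def cochran_q(bx: np.ndarray, by: np.ndarray, sy: np.ndarray, theta: float) -> float:
    return float(np.sum((by - theta * bx) ** 2 / sy**2))


def mr_ivw(instruments: pd.DataFrame) -> MrResult:
    """Inverse-variance weighted estimate with first-order weights 1/se_outcome^2."""
    bx, _, by, sy = _extract(instruments)
    n = bx.size
    if n < 2:
        raise ValueError("IVW requires at least 2 instruments")
    w = bx**2 / sy**2
    theta = float(np.sum(bx * by / sy**2) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    model = "fixed"
    q = cochran_q(bx, by, sy, theta)
    if n > 2 and q / (n - 1) > 1.0:
        se *= math.sqrt(q / (n - 1))
        model = "random"
    p = 2.0 * sps.norm.sf(abs(theta) / se)
    return MrResult("IVW", theta, se, float(p), n, model=model)


def mr_egger(instruments: pd.DataFrame) -> MrResult:
    """MR-Egger weighted regression of outcome on exposure betas with an
    unconstrained intercept capturing directional pleiotropy."""
    bx, _, by, sy = _extract(instruments)
    n = bx.size
    if n < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    bx, by = _orient_positive(bx, by)
    import statsmodels.api as sm

    model = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy**2).fit()
    # multiplicative random effects: residual scale never deflates below 1
    scale = max(1.0, math.sqrt(model.scale))
    se_int, se_slope = (model.bse / math.sqrt(model.scale)) * scale
    intercept, slope = model.params
    df = n - 2
    p_slope = 2.0 * sps.t.sf(abs(slope) / se_slope, df)
    p_int = 2.0 * sps.t.sf(abs(intercept) / se_int, df)
    return MrResult(
        "MR-Egger",
        float(slope),
        float(se_slope),
        float(p_slope),
        n,
        intercept=float(intercept),
        se_intercept=float(se_int),
        p_intercept=float(p_int),
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted 50th percentile with the standard interpolation on
    cumulative weights centred at each observation."""
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= np.sum(w)
    return float(np.interp(0.5, cum, v))


def mr_median(
    instruments: pd.DataFrame,
    weighted: bool = True,
    n_boot: int = 10_000,
    seed: int = 2_021,
) -> MrResult:
    """Simple or weighted median of per-variant Wald ratios.

    The simple median is the equally-weighted weighted median; the weighted
    variant uses inverse-variance weights bx^2/sy^2 of the ratios.  The SE
    comes from a seeded parametric bootstrap over both beta columns.
    """
    bx, sx, by, sy = _extract(instruments)
    n = bx.size
    if n < 3:
        raise ValueError("median estimators require at least 3 instruments")
    bx, by = _orient_positive(bx, by)

    def estimate(bx_s: np.ndarray, by_s: np.ndarray) -> float:
        ratios = by_s / bx_s
        w = (bx_s**2 / sy**2) if weighted else np.ones(n)
        return _weighted_median(ratios, w)

    theta = estimate(bx, by)
    rng = np.random.default_rng(seed)
    draws = np.empty(n_boot)
    for b in range(n_boot):
        draws[b] = estimate(bx + rng.normal(0.0, sx), by + rng.normal(0.0, sy))
    se = float(np.std(draws, ddof=1))
    p = 2.0 * sps.norm.sf(abs(theta) / se) if se > 0 else 0.0
    name = "Weighted median" if weighted else "Simple median"
    return MrResult(name, float(theta), se, float(p), n)


def _profile_neg_loglik(theta: float, bx, sx, by, sy) -> float:
    """Negative joint-normal log-likelihood profiled over the true exposure
    effects xi_j (quadratic, so the profile is closed-form)."""
    xi = (bx / sx**2 + theta * by / sy**2) / (1.0 / sx**2 + theta**2 / sy**2)
    return float(
        0.5 * np.sum((bx - xi) ** 2 / sx**2) + 0.5 * np.sum((by - theta * xi) ** 2 / sy**2)
    )


def mr_maxlik(instruments: pd.DataFrame) -> MrResult:
    """Maximum-likelihood estimate under a joint normal model for the
    observed exposure and outcome betas; reduces to IVW when the exposure
    betas are measured without heterogeneity."""
    bx, sx, by, sy = _extract(instruments)
    n = bx.size
    if n < 2:
        raise ValueError("maximum likelihood requires at least 2 instruments")
    ivw_start = float(np.sum(bx * by / sy**2) / np.sum(bx**2 / sy**2))
    span = 10.0 * (abs(ivw_start) + 1.0)
    res = minimize_scalar(
        _profile_neg_loglik,
        bounds=(ivw_start - span, ivw_start + span),
        args=(bx, sx, by, sy),
        method="bounded",
        options={"xatol": 1e-12},
    )
    if not res.success or not np.isfinite(res.x) or abs(res.x - ivw_start) >= span:
        raise RuntimeError(
            f"maximum-likelihood MR failed to converge (start={ivw_start:.4g}, result={res})"
        )
    theta = float(res.x)
    # observed information from the profile curvature
    h = 1e-5 * (abs(theta) + 1.0)
    curv = (
        _profile_neg_loglik(theta + h, bx, sx, by, sy)
        - 2.0 * _profile_neg_loglik(theta, bx, sx, by, sy)
        + _profile_neg_loglik(theta - h, bx, sx, by, sy)
    ) / h**2
    if curv <= 0:
        raise RuntimeError("non-positive observed information in maximum-likelihood MR")
    se = float(1.0 / math.sqrt(curv))
    p = 2.0 * sps.norm.sf(abs(theta) / se)
    return MrResult("Maximum-likelihood", theta, se, float(p), n)


# ---------------------------------------------------------------------------
# pleiotropy screening
# ---------------------------------------------------------------------------


def benjamini_hochberg(pvalues: np.ndarray, fdr: float) -> np.ndarray:
    """Boolean rejection mask of the BH step-up procedure at level ``fdr``."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p)
    thresholds = fdr * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresholds
    reject = np.zeros(m, dtype=bool)
    if passed.any():
        kmax = int(np.max(np.nonzero(passed)[0]))
        reject[order[: kmax + 1]] = True
    return reject


def pleiotropy_filter(
    instruments: pd.DataFrame, fdr: float = 0.2
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Remove variants with heterogeneous exposure-outcome effects.

    For each variant the consensus effect is re-fit on the remaining
    variants and the held-out squared residual, scaled by its variance
    sy_j^2 + theta^2 sx_j^2, is referred to chi-square(1);
    Benjamini-Hochberg at ``fdr`` flags variants for removal.  The
    leave-one-out consensus is the weighted median of Wald ratios rather
    than IVW: when several variants share large pleiotropic effects an IVW
    consensus is dragged toward the outliers and masks them (and flags the
    clean variants instead), while the median keeps its breakdown point.
    Returns (kept, removed, per-variant p-values).
    """
    bx, sx, by, sy = _extract(instruments)
    n = bx.size
    if n < 4:
        raise ValueError("pleiotropy screening requires at least 4 instruments")
    bxo, byo = _orient_positive(bx, by)
    ratios = byo / bxo
    weights = bxo**2 / sy**2
    pvals = np.empty(n)
    for j in range(n):
        mask = np.ones(n, dtype=bool)
        mask[j] = False
        theta_j = _weighted_median(ratios[mask], weights[mask])
        resid_var = sy[j] ** 2 + (theta_j * sx[j]) ** 2
        q_j = (byo[j] - theta_j * bxo[j]) ** 2 / resid_var
        pvals[j] = sps.chi2.sf(q_j, 1)
    reject = benjamini_hochberg(pvals, fdr)
    pseries = pd.Series(pvals, index=instruments.index, name="pleiotropy_p")
    kept = instruments.loc[~reject].reset_index(drop=True)
    removed = instruments.loc[reject].reset_index(drop=True)
    return kept, removed, pseries


def mr_report(
    instruments: pd.DataFrame,
    fdr: float = 0.2,
    median_boot: int = 10_000,
    median_seed: int = 2_021,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full estimator suite after pleiotropy pruning.

    Returns (report, removed) where the report mirrors the usual MR summary
    table: method, OR with 95% CI (outcome betas exponentiated from the
    log-odds scale), p-value, plus the Egger intercept row.
    """
    kept, removed, _ = pleiotropy_filter(instruments, fdr=fdr)
    if len(kept) < 3:
        raise ValueError("fewer than 3 instruments remain after pleiotropy pruning")
    results = [
        mr_maxlik(kept),
        mr_median(kept, weighted=False, n_boot=median_boot, seed=median_seed),
        mr_median(kept, weighted=True, n_boot=median_boot, seed=median_seed),
        mr_ivw(kept),
    ]
    egger = mr_egger(kept)
    rows = [r.odds_ratio_row() for r in results] + [egger.odds_ratio_row()]
    lo = egger.intercept - 1.959964 * egger.se_intercept
    hi = egger.intercept + 1.959964 * egger.se_intercept
    rows.append(
        {
            "method": "Egger intercept",
            "or": math.exp(egger.intercept),
            "or_lo": math.exp(lo),
            "or_hi": math.exp(hi),
            "p_value": egger.p_intercept,
        }
    )
    return pd.DataFrame(rows), removed
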