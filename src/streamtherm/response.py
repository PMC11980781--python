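"""Per-taxon thermal response estimation.

Three complementary measures of a taxon's thermal niche along the MWMT
gradient:

* **central tendency** — abundance-weighted average (WA) optimum and the
  matching weighted standard deviation (tolerance);
* **thermal limits** — 10th and 90th percentiles of MWMT at occurrences,
  trimming outliers at both ends;
* **response shape** — a binomial GAM of presence/absence on MWMT
  (probability of capture, POC) classified into seven curve-shape
  categories.

:class:`ThermalResponseModel` runs all three for every taxon of a prepared
dataset and returns a :class:`ThermalResponseResults` with a tidy
per-taxon table and the fitted curves.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.gam.api import BSplines, GLMGam

logger = logging.getLogger(__name__)

__all__ = [
    "SHAPE_CATEGORIES",
    "GamFit",
    "ThermalResponse",
    "wa_stats",
    "occurrence_limits",
    "fit_gam",
    "classify_shape",
    "ThermalResponseModel",
    "ThermalResponseResults",
]

#: The seven thermal response curve shapes.
SHAPE_CATEGORIES = (
    "decreaser",
    "increaser",
    "unimodal",
    "uni_decreaser",
    "uni_increaser",
    "flat",
    "unclear",
)


def wa_stats(mwmt, weights) -> tuple[float, float]:
    """Weighted-average optimum and tolerance.

    optimum = Σ w_i x_i / Σ w_i ; tolerance = sqrt(Σ w_i (x_i − opt)² / Σ w_i).

    Weights are taxon relative abundances per sample; samples where the
    taxon is absent carry zero weight and drop out of both sums.
    """
    x = np.asarray(mwmt, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.shape != w.shape:
        raise ValueError("mwmt and weights must have the same shape")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    sw = w.sum()
    if sw <= 0:
        raise ValueError("all weights are zero: optimum undefined")
    opt = float((w * x).sum() / sw)
    tol = float(np.sqrt((w * (x - opt) ** 2).sum() / sw))
    return opt, tol


def occurrence_limits(mwmt_at_presence, p_lo: float = 0.10, p_hi: float = 0.90):
    """Lower/upper occurrence limits as linear-interpolation percentiles.

    Uses the ``h = (n-1)p + 1`` convention (numpy's ``linear`` method).
    """
    x = np.asarray(mwmt_at_presence, dtype=float)
    if x.size == 0:
        raise ValueError("no occurrences: limits undefined")
    lo, hi = np.quantile(x, [p_lo, p_hi], method="linear")
    return float(lo), float(hi)


@dataclass
class GamFit:
    """A fitted probability-of-capture curve on a temperature grid.

    ``binned_poc`` holds (bin-midpoint, mean presence) pairs from raw data
    in equal-width MWMT bins; it is a visualization aid only and feeds no
    downstream computation.
    """

    grid: np.ndarray
    poc: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    binned_poc: list[tuple[float, float]]
    method: str = "gam"  # gam | quadratic_logistic | degenerate

    @property
    def max_poc(self) -> float:
        return float(self.poc.max())


def _binned_occurrence(presence, mwmt, n_bins):
    x = np.asarray(mwmt, float)
    y = np.asarray(presence, float)
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.digitize(x, edges[1:-1]), 0, n_bins - 1)
    out = []
    for b in range(n_bins):
        mask = idx == b
        if mask.any():
            out.append((float(mids[b]), float(y[mask].mean())))
    return out


def _design_matrix(smoother, grid):
    basis = smoother.transform(np.asarray(grid, float)[:, None])
    return np.column_stack([np.ones(len(grid)), basis])


def fit_gam(
    presence,
    mwmt,
    grid_size: int = 100,
    ci: float = 0.90,
    df: int = 8,
    n_bins: int = 10,
    alphas=None,
) -> GamFit:
    """Binomial spline smooth of presence/absence on MWMT.

    A penalized cubic B-spline GAM; the penalty weight is chosen by AIC
    over a log-spaced grid. Pointwise confidence intervals come from the
    coefficient covariance on the link (logit) scale, then are mapped to
    the response scale. On non-convergence the fit falls back to a
    logistic regression with a quadratic term (logged).
    """
    y = np.asarray(presence, float)
    x = np.asarray(mwmt, float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("presence must be 0/1")
    grid = np.linspace(x.min(), x.max(), grid_size)
    binned = _binned_occurrence(y, x, n_bins)
    from scipy.stats import norm

    zval = norm.ppf(0.5 + ci / 2.0)

    if y.min() == y.max():  # single class: constant curve, no uncertainty model
        p = float(y.mean())
        const = np.full(grid_size, p)
        return GamFit(grid, const, const.copy(), const.copy(), binned, method="degenerate")

    try:
        smoother = BSplines(x[:, None], df=[df], degree=[3])
        exog = np.ones((len(x), 1))
        if alphas is None:
            alphas = np.logspace(-1, 4, 6)
        best = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for a in np.atleast_1d(alphas):
                res = GLMGam(
                    y, exog=exog, smoother=smoother,
                    family=sm.families.Binomial(), alpha=[float(a)],
                ).fit(maxiter=100)
                if not np.all(np.isfinite(res.params)):
                    continue
                if best is None or res.aic < best[0]:
                    best = (res.aic, res)
        if best is None:
            raise RuntimeError("no GAM fit converged")
        res = best[1]
        X = _design_matrix(smoother, grid)
        eta = X @ res.params
        se = np.sqrt(np.einsum("ij,jk,ik->i", X, np.asarray(res.cov_params()), X))
        method = "gam"
    except Exception as e:  # pragma: no cover - exercised via degenerate inputs
        logger.warning("GAM failed (%s); falling back to quadratic logistic", e)
        X_all = np.column_stack([np.ones_like(x), x, x**2])
        res = sm.GLM(y, X_all, family=sm.families.Binomial()).fit()
        X = np.column_stack([np.ones_like(grid), grid, grid**2])
        eta = X @ res.params
        se = np.sqrt(np.einsum("ij,jk,ik->i", X, np.asarray(res.cov_params()), X))
        method = "quadratic_logistic"

    poc = expit(eta)
    ci_lo = expit(eta - zval * se)
    ci_hi = expit(eta + zval * se)
    return GamFit(grid, poc, ci_lo, ci_hi, binned, method=method)


def classify_shape(
    fit: GamFit,
    flat_range: float = 0.02,
    unclear_poc: float = 0.15,
    unclear_ci: float = 0.10,
    slope_majority: float = 0.75,
    endpoint_frac: float = 0.25,
    shoulder_frac: float = 0.50,
) -> str:
    """Classify a fitted POC curve into one of the seven shape categories.

    Decision sequence:

    1. *flat* — range of POC over the grid below ``flat_range``;
    2. *unclear* — maximum POC below ``unclear_poc`` while every CI width
       stays below ``unclear_ci`` (a confidently negligible response);
    3. *decreaser*/*increaser* — at least ``slope_majority`` of grid
       slopes share one sign;
    4. *unimodal* — interior maximum with both endpoints below
       ``endpoint_frac`` of the peak; *uni_decreaser* — warm endpoint
       below ``endpoint_frac`` of the peak but cold endpoint still at
       least ``shoulder_frac`` of it (a cold shoulder with a sharp warm
       decline); *uni_increaser* mirrored;
    5. otherwise *unclear* (conflicting slope signs).
    """
    poc = np.asarray(fit.poc, float)
    rng = poc.max() - poc.min()
    if rng < flat_range:
        return "flat"
    widths = np.asarray(fit.ci_hi, float) - np.asarray(fit.ci_lo, float)
    if poc.max() < unclear_poc and widths.max() < unclear_ci:
        return "unclear"
    slopes = np.diff(poc)
    nz = slopes[slopes != 0]
    if nz.size:
        frac_neg = (nz < 0).mean()
        frac_pos = (nz > 0).mean()
        if frac_neg >= slope_majority:
            return "decreaser"
        if frac_pos >= slope_majority:
            return "increaser"
    peak = poc.max()
    cold, warm = poc[0], poc[-1]
    cold_low = cold < endpoint_frac * peak
    warm_low = warm < endpoint_frac * peak
    if cold_low and warm_low:
        return "unimodal"
    if warm_low and cold >= shoulder_frac * peak:
        return "uni_decreaser"
    if cold_low and warm >= shoulder_frac * peak:
        return "uni_increaser"
    return "unclear"


@dataclass
class ThermalResponse:
    """Per-taxon thermal response summary."""

    taxon_id: str
    n_occ: int
    wa_optimum: float
    wa_tolerance: float
    p10: float
    p90: float
    shape: str
    max_poc: float
    shape_overridden: bool = False


class ThermalResponseModel:
    """Estimate thermal responses for every taxon of a prepared dataset.

    Parameters
    ----------
    long_table : DataFrame
        Tidy table with columns ``sample_id, mwmt, taxon_id, count,
        rel_abund, presence`` — one row per (sample, taxon) occurrence,
        as produced by :meth:`streamtherm.prep.PrepResult.long_table`.
    mwmt : Series
        MWMT per sample_id, covering all prepared samples (needed so that
        absences contribute zeros to the GAM).
    min_occ : int
        Taxa occurring in fewer samples are skipped.
    """

    def __init__(
        self,
        long_table: pd.DataFrame,
        mwmt: pd.Series,
        *,
        min_occ: int = 1,
        grid_size: int = 100,
        ci: float = 0.90,
        fit_gams: bool = True,
        shape_overrides: dict[str, str] | None = None,
    ) -> None:
        required = {"sample_id", "mwmt", "taxon_id", "rel_abund", "presence"}
        missing = required - set(long_table.columns)
        if missing:
            raise ValueError(f"long_table missing columns: {sorted(missing)}")
        self.long_table = long_table
        self.mwmt = mwmt.astype(float)
        self.min_occ = min_occ
        self.grid_size = grid_size
        self.ci = ci
        self.fit_gams = fit_gams
        self.shape_overrides = dict(shape_overrides or {})
        bad = set(self.shape_overrides.values()) - set(SHAPE_CATEGORIES)
        if bad:
            raise ValueError(f"unknown shape override categories: {sorted(bad)}")

    @classmethod
    def from_prep(cls, prep_result, dataset, **kwargs) -> "ThermalResponseModel":
        return cls(prep_result.long_table(dataset), prep_result.mwmt_series(), **kwargs)

    def fit(self) -> "ThermalResponseResults":
        sample_ids = self.mwmt.index.to_numpy()
        x_all = self.mwmt.to_numpy()
        pos = {sid: i for i, sid in enumerate(sample_ids)}

        responses: list[ThermalResponse] = []
        gam_fits: dict[str, GamFit] = {}
        for taxon_id, g in self.long_table.groupby("taxon_id", sort=True):
            present = g[g["presence"] == 1]
            n_occ = len(present)
            if n_occ < self.min_occ:
                continue
            opt, tol = wa_stats(present["mwmt"], present["rel_abund"])
            p10, p90 = occurrence_limits(present["mwmt"])
            shape, max_poc, overridden = "unclear", float("nan"), False
            if self.fit_gams:
                y = np.zeros(len(sample_ids))
                for sid in present["sample_id"]:
                    y[pos[sid]] = 1.0
                gf = fit_gam(y, x_all, grid_size=self.grid_size, ci=self.ci)
                gam_fits[taxon_id] = gf
                shape = classify_shape(gf)
                max_poc = gf.max_poc
                if taxon_id in self.shape_overrides:
                    shape = self.shape_overrides[taxon_id]
                    overridden = True
            responses.append(
                ThermalResponse(
                    taxon_id=taxon_id, n_occ=n_occ, wa_optimum=opt,
                    wa_tolerance=tol, p10=p10, p90=p90, shape=shape,
                    max_poc=max_poc, shape_overridden=overridden,
                )
            )
        return ThermalResponseResults(self, responses, gam_fits)


class ThermalResponseResults:
    """Fitted per-taxon thermal responses."""

    def __init__(self, model, responses, gam_fits):
        self.model = model
        self.responses = {r.taxon_id: r for r in responses}
        self.gam_fits = gam_fits

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "taxon_id": r.taxon_id,
                    "n_occ": r.n_occ,
                    "wa_optimum": r.wa_optimum,
                    "wa_tolerance": r.wa_tolerance,
                    "p10": r.p10,
                    "p90": r.p90,
                    "shape": r.shape,
                    "max_poc": r.max_poc,
                    "shape_overridden": r.shape_overridden,
                }
                for r in self.responses.values()
            ]
        ).sort_values("taxon_id").reset_index(drop=True)

    def curves_table(self) -> pd.DataFrame:
        """Long table of fitted POC curves (taxon, grid point, poc, CI)."""
        frames = []
        for taxon_id, gf in sorted(self.gam_fits.items()):
            frames.append(
                pd.DataFrame(
                    {
                        "taxon_id": taxon_id,
                        "mwmt": gf.grid,
                        "poc": gf.poc,
                        "ci_lo": gf.ci_lo,
                        "ci_hi": gf.ci_hi,
                    }
                )
            )
        if not frames:
            return pd.DataFrame(columns=["taxon_id", "mwmt", "poc", "ci_lo", "ci_hi"])
        return pd.concat(frames, ignore_index=True)

    def summary(self) -> str:
        t = self.table
        lines = [
            "Thermal response estimates",
            "==========================",
            f"taxa: {len(t)}   GAM curves: {len(self.gam_fits)}",
        ]
        if len(t):
            lines.append(
                f"WA optimum range: {t.wa_optimum.min():.2f}-{t.wa_optimum.max():.2f} degC"
            )
            counts = t["shape"].value_counts()
            lines.append("shapes: " + ", ".join(f"{k}={v}" for k, v in counts.items()))
        return "\n".join(lines)
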