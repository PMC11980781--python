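"""The Macroinvertebrate Thermal Tolerance Index (MTTI).

An assemblage-level index on the MWMT scale (°C), built by two-step
weighted-averaging (WA) calibration and regression:

*calibration* — each operational taxonomic unit (OTU) gets a thermal
optimum u_k (abundance-weighted mean MWMT) and tolerance t_k (weighted
SD); *regression* — a sample's raw score is the abundance-weighted mean
of the optima of the OTUs it contains, optionally downweighting
broad-tolerance OTUs by 1/t_k²:

    x̂0_j = Σ_k y_jk u_k / t_k²  ÷  Σ_k y_jk / t_k²

Double averaging shrinks raw scores toward the gradient centre, so a
*deshrinking* regression spreads them back out: *classical* regresses
x̂0 on observed MWMT (x̂0 = a + b·x) and reports (x̂0 − a)/b; *inverse*
regresses MWMT on x̂0.

:class:`MTTIModel` wraps this as a fit/results pair with apparent and
bootstrap cross-validated performance (RMSEP, R², maximum bias).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import compute_distinctness

__all__ = [
    "OTUTable",
    "build_otu_table",
    "stratified_split",
    "ModelPerformance",
    "performance",
    "MTTIModel",
    "MTTIResults",
]


# ---------------------------------------------------------------------------
# OTU table construction
# ---------------------------------------------------------------------------

@dataclass
class OTUTable:
    """Sample-by-OTU count matrix with its provenance."""

    counts: pd.DataFrame  # index sample_id, columns otu_id
    mwmt: pd.Series  # per retained sample
    unit: pd.Series  # processing-unit label per retained sample
    otu_map: dict[str, str]
    n_dropped_low_count: int
    n_unmapped_taxa: int


def build_otu_table(
    samples,
    otu_map: dict[str, str],
    dataset,
    min_count: int = 150,
) -> OTUTable:
    """Aggregate sample counts into OTUs, dropping ambiguous records.

    Per sample: remove non-distinct taxa (those whose descendant is also
    present), map the remaining taxa through ``otu_map`` (unmapped taxa
    are dropped and counted), sum counts per OTU, then drop samples whose
    remaining total is below ``min_count``.
    """
    rows: dict[str, dict[str, int]] = {}
    mwmt: dict[str, float] = {}
    unit: dict[str, str] = {}
    unmapped: set[str] = set()
    n_dropped = 0
    for s in samples:
        distinct = compute_distinctness(s.counts, dataset)
        agg: dict[str, int] = {}
        for t in distinct:
            otu = otu_map.get(t)
            if otu is None:
                unmapped.add(t)
                continue
            agg[otu] = agg.get(otu, 0) + s.counts[t]
        if sum(agg.values()) < min_count:
            n_dropped += 1
            continue
        rows[s.sample_id] = agg
        mwmt[s.sample_id] = s.mwmt
        unit[s.sample_id] = s.unit
    counts = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    counts = counts.sort_index().sort_index(axis=1)
    return OTUTable(
        counts=counts,
        mwmt=pd.Series(mwmt).loc[counts.index],
        unit=pd.Series(unit).loc[counts.index],
        otu_map=dict(otu_map),
        n_dropped_low_count=n_dropped,
        n_unmapped_taxa=len(unmapped),
    )


# ---------------------------------------------------------------------------
# Calibration / validation split
# ---------------------------------------------------------------------------

def stratified_split(
    mwmt: pd.Series,
    unit: pd.Series,
    frac: float = 0.10,
    n_bins: int = 5,
    seed: int | None = None,
) -> pd.Series:
    """Assign samples to CAL/VAL strata by unit and temperature quantile.

    Within each processing unit, MWMT values are cut into ``n_bins``
    quantile bins (units with fewer than ``n_bins`` samples form a single
    bin); within each (unit, bin) stratum, ``round(frac × n)`` samples are
    drawn without replacement into VAL. Returns a Series of "CAL"/"VAL"
    labels indexed like ``mwmt``.
    """
    rng = np.random.default_rng(seed)
    labels = pd.Series("CAL", index=mwmt.index, dtype=object)
    for u in sorted(unit.unique()):
        idx = unit.index[unit == u]
        vals = mwmt.loc[idx]
        if len(idx) < n_bins:
            bins = pd.Series(0, index=idx)
        else:
            bins = pd.qcut(vals, q=n_bins, labels=False, duplicates="drop")
        for _, members in bins.groupby(bins):
            ids = np.array(sorted(members.index))
            n_val = int(np.floor(frac * len(ids) + 0.5))  # round half up
            if n_val == 0:
                continue
            chosen = rng.choice(ids, size=n_val, replace=False)
            labels.loc[chosen] = "VAL"
    return labels


# ---------------------------------------------------------------------------
# Performance statistics
# ---------------------------------------------------------------------------

@dataclass
class ModelPerformance:
    """RMSEP, R² and maximum bias of predictions against observations."""

    rmsep: float
    r2: float
    max_bias: float
    n: int

    def as_dict(self) -> dict:
        return {"rmsep": self.rmsep, "r2": self.r2, "max_bias": self.max_bias, "n": self.n}


def performance(
    predicted,
    observed,
    n_segments: int = 10,
    segment_range: tuple[float, float] | None = None,
) -> ModelPerformance:
    """Prediction-error statistics along the thermal gradient.

    * RMSEP — root-mean-square of (pred − obs);
    * R² — squared Pearson correlation of pred and obs;
    * maximum bias — divide the observed gradient into ``n_segments``
      equal-width segments (range from ``segment_range`` when given, e.g.
      the calibration range when evaluating validation data) and take the
      largest absolute mean residual in any populated segment.
    """
    pred = np.asarray(predicted, float)
    obs = np.asarray(observed, float)
    mask = np.isfinite(pred) & np.isfinite(obs)
    pred, obs = pred[mask], obs[mask]
    if len(obs) < n_segments:
        raise ValueError(f"need at least {n_segments} pairs, got {len(obs)}")
    if np.var(obs) == 0:
        raise ValueError("observed values have zero variance: R2 undefined")
    rmsep = float(np.sqrt(np.mean((pred - obs) ** 2)))
    r2 = float(stats.pearsonr(pred, obs)[0] ** 2)
    lo, hi = segment_range if segment_range is not None else (obs.min(), obs.max())
    edges = np.linspace(lo, hi, n_segments + 1)
    idx = np.clip(np.digitize(obs, edges[1:-1]), 0, n_segments - 1)
    resid = pred - obs
    max_bias = 0.0
    for b in range(n_segments):
        m = idx == b
        if m.any():
            max_bias = max(max_bias, abs(float(resid[m].mean())))
    return ModelPerformance(rmsep=rmsep, r2=r2, max_bias=max_bias, n=len(obs))


# ---------------------------------------------------------------------------
# The WA calibration model
# ---------------------------------------------------------------------------

def _wa_fit_core(Y: np.ndarray, x: np.ndarray, downweight: bool,
                 tol_floor_quantile: float, tol_floor_abs: float):
    """Vectorized WA calibration: optima, floored tolerances, raw scores."""
    rowsum = Y.sum(axis=1, keepdims=True)
    if np.any(rowsum == 0):
        raise ValueError("samples with zero total abundance in calibration data")
    R = Y / rowsum  # relative abundances
    colsum = R.sum(axis=0)
    present = colsum > 0
    u = np.full(Y.shape[1], np.nan)
    t = np.full(Y.shape[1], np.nan)
    u[present] = (R[:, present] * x[:, None]).sum(axis=0) / colsum[present]
    sq = (R[:, present] * (x[:, None] - u[present]) ** 2).sum(axis=0) / colsum[present]
    t[present] = np.sqrt(np.maximum(sq, 0.0))
    floor = max(float(np.nanquantile(t, tol_floor_quantile)), tol_floor_abs)
    t_floored = np.maximum(t, floor)
    w = 1.0 / t_floored**2 if downweight else np.ones_like(t_floored)
    num = R[:, present] @ (u[present] * w[present])
    den = R[:, present] @ w[present]
    x0 = num / den
    return u, t_floored, floor, x0


class MTTIModel:
    """Weighted-averaging calibration model for the MTTI.

    Parameters
    ----------
    counts : DataFrame
        Sample-by-OTU abundance matrix (raw or relative; the index scale
        cancels within each sample).
    mwmt : Series
        Observed MWMT per sample (°C), aligned with ``counts``.
    downweight : bool
        Weight each OTU by the inverse square of its tolerance in the
        regression step.
    deshrink : {"classical", "inverse", "none"}
    tol_floor_quantile : float
        Tolerances below this quantile of the tolerance distribution are
        raised to it (with an absolute minimum of 0.01 °C), preventing
        near-zero tolerances of rare OTUs from dominating downweighting.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        mwmt: pd.Series,
        *,
        downweight: bool = True,
        deshrink: str = "classical",
        tol_floor_quantile: float = 0.05,
        tol_floor_abs: float = 0.01,
    ) -> None:
        if deshrink not in ("classical", "inverse", "none"):
            raise ValueError(f"unknown deshrink method {deshrink!r}")
        mwmt = mwmt.loc[counts.index].astype(float)
        if counts.shape[1] < 2 or counts.shape[0] < 10:
            raise ValueError("need at least 2 OTUs and 10 samples to calibrate")
        self.counts = counts.astype(float)
        self.mwmt = mwmt
        self.downweight = downweight
        self.deshrink = deshrink
        self.tol_floor_quantile = tol_floor_quantile
        self.tol_floor_abs = tol_floor_abs

    @classmethod
    def from_otu_table(cls, otu_table: OTUTable, subset=None, **kwargs) -> "MTTIModel":
        counts, mwmt = otu_table.counts, otu_table.mwmt
        if subset is not None:
            counts, mwmt = counts.loc[subset], mwmt.loc[subset]
        return cls(counts, mwmt, **kwargs)

    def fit(self) -> "MTTIResults":
        Y = self.counts.to_numpy()
        x = self.mwmt.to_numpy()
        u, t, floor, x0 = _wa_fit_core(
            Y, x, self.downweight, self.tol_floor_quantile, self.tol_floor_abs
        )
        if self.deshrink == "classical":
            b, a = np.polyfit(x, x0, 1)
            if abs(b) < 1e-12:
                raise ValueError("deshrinking regression is singular (slope ~ 0)")
            fitted = (x0 - a) / b
        elif self.deshrink == "inverse":
            b, a = np.polyfit(x0, x, 1)
            fitted = a + b * x0
        else:
            a, b = 0.0, 1.0
            fitted = x0
        return MTTIResults(
            model=self,
            optima=pd.Series(u, index=self.counts.columns, name="optimum"),
            tolerances=pd.Series(t, index=self.counts.columns, name="tolerance"),
            tolerance_floor=floor,
            deshrink_a=float(a),
            deshrink_b=float(b),
            raw_scores=pd.Series(x0, index=self.counts.index, name="raw_score"),
            fittedvalues=pd.Series(fitted, index=self.counts.index, name="mtti"),
        )


class MTTIResults:
    """Fitted MTTI model: OTU coefficients, deshrinking line, diagnostics."""

    def __init__(self, model, optima, tolerances, tolerance_floor,
                 deshrink_a, deshrink_b, raw_scores, fittedvalues):
        self.model = model
        self.optima = optima
        self.tolerances = tolerances
        self.tolerance_floor = tolerance_floor
        self.deshrink_a = deshrink_a
        self.deshrink_b = deshrink_b
        self.raw_scores = raw_scores
        self.fittedvalues = fittedvalues
        self.training_range = (float(model.mwmt.min()), float(model.mwmt.max()))

    # -- prediction --------------------------------------------------------

    def _raw_score(self, y: pd.Series) -> tuple[float, float, int]:
        """Raw WA score, abundance coverage, and OTU count for one sample."""
        known = set(self.optima.dropna().index)
        shared = [otu for otu in y.index if otu in known and y[otu] > 0]
        total = float(y.sum())
        if total <= 0:
            return np.nan, 0.0, 0
        cover = float(y[shared].sum()) / total if shared else 0.0
        if not shared:
            return np.nan, cover, 0
        u = self.optima[shared].to_numpy()
        t = self.tolerances[shared].to_numpy()
        w = 1.0 / t**2 if self.model.downweight else np.ones_like(t)
        r = y[shared].to_numpy() / total
        return float((r * u * w).sum() / (r * w).sum()), cover, len(shared)

    def predict(self, counts: pd.DataFrame) -> pd.DataFrame:
        """Predict the MTTI for new samples.

        ``counts`` is a sample-by-OTU matrix; OTUs unknown to the model
        are ignored but reported through the ``coverage`` column (share
        of individuals belonging to model OTUs). Samples sharing no OTU
        with the model get a missing MTTI.
        """
        rows = []
        for sid, y in counts.iterrows():
            x0, cover, n_otus = self._raw_score(y)
            if np.isnan(x0):
                mtti = np.nan
            elif self.model.deshrink == "classical":
                mtti = (x0 - self.deshrink_a) / self.deshrink_b
            elif self.model.deshrink == "inverse":
                mtti = self.deshrink_a + self.deshrink_b * x0
            else:
                mtti = x0
            rows.append({"sample_id": sid, "mtti": mtti, "n_otus_used": n_otus,
                         "coverage": cover})
        return pd.DataFrame(rows).set_index("sample_id")

    # -- performance -------------------------------------------------------

    def apparent_performance(self, n_segments: int = 10) -> ModelPerformance:
        """Performance of in-sample (calibration) predictions."""
        return performance(self.fittedvalues, self.model.mwmt,
                           n_segments=n_segments, segment_range=self.training_range)

    def validate(self, counts: pd.DataFrame, mwmt: pd.Series,
                 n_segments: int = 10) -> ModelPerformance:
        """Performance on an independent validation set.

        Maximum-bias segments reuse the calibration gradient range so CAL
        and VAL biases are comparable.
        """
        pred = self.predict(counts)["mtti"]
        return performance(pred, mwmt.loc[pred.index],
                           n_segments=n_segments, segment_range=self.training_range)

    def bootstrap_cv(self, n_boot: int = 1000, seed: int | None = None,
                     n_segments: int = 10) -> ModelPerformance:
        """Bootstrap cross-validated performance.

        Each replicate refits the full model (optima, tolerances,
        deshrinking) on a bootstrap resample of the calibration samples
        and predicts the out-of-bag samples; per-sample out-of-bag
        predictions are averaged across replicates and the pooled
        (mean prediction, observation) pairs scored. Degenerate replicate
        fits are skipped and counted in ``n_skipped``.
        """
        rng = np.random.default_rng(seed)
        Y = self.model.counts.to_numpy()
        x = self.model.mwmt.to_numpy()
        n = len(x)
        pred_sum = np.zeros(n)
        pred_cnt = np.zeros(n)
        self.n_skipped_replicates = 0
        for _ in range(n_boot):
            boot = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), boot)
            if oob.size == 0:
                continue
            try:
                u, t, _, x0 = _wa_fit_core(
                    Y[boot], x[boot], self.model.downweight,
                    self.model.tol_floor_quantile, self.model.tol_floor_abs,
                )
                if self.model.deshrink == "classical":
                    b, a = np.polyfit(x[boot], x0, 1)
                    if abs(b) < 1e-12:
                        raise ValueError("singular deshrink")
                elif self.model.deshrink == "inverse":
                    b, a = np.polyfit(x0, x[boot], 1)
                else:
                    a, b = 0.0, 1.0
                present = ~np.isnan(u)
                w = (1.0 / t**2) if self.model.downweight else np.ones_like(t)
                Yo = Y[oob][:, present]
                rows = Yo.sum(axis=1)
                ok = rows > 0
                num = Yo @ (u[present] * w[present])
                den = Yo @ w[present]
                x0_oob = np.full(oob.size, np.nan)
                x0_oob[ok] = num[ok] / den[ok]
                if self.model.deshrink == "classical":
                    p = (x0_oob - a) / b
                elif self.model.deshrink == "inverse":
                    p = a + b * x0_oob
                else:
                    p = x0_oob
            except (ValueError, np.linalg.LinAlgError):
                self.n_skipped_replicates += 1
                continue
            good = oob[np.isfinite(p)]
            pred_sum[good] += p[np.isfinite(p)]
            pred_cnt[good] += 1
        covered = pred_cnt > 0
        mean_pred = pred_sum[covered] / pred_cnt[covered]
        return performance(mean_pred, x[covered], n_segments=n_segments,
                           segment_range=self.training_range)

    # -- reporting ---------------------------------------------------------

    def params_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"otu_id": self.optima.index, "optimum": self.optima.to_numpy(),
             "tolerance": self.tolerances.to_numpy()}
        )

    def to_json_dict(self) -> dict:
        return {
            "downweight": self.model.downweight,
            "deshrink": self.model.deshrink,
            "deshrink_a": self.deshrink_a,
            "deshrink_b": self.deshrink_b,
            "tolerance_floor": self.tolerance_floor,
            "training_range": list(self.training_range),
            "optima": {k: (None if np.isnan(v) else float(v))
                       for k, v in self.optima.items()},
            "tolerances": {k: float(v) for k, v in self.tolerances.items()},
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "MTTIResults":
        """Rebuild a prediction-capable results object from its JSON form."""
        optima = pd.Series(d["optima"], dtype=float)
        tolerances = pd.Series(d["tolerances"], dtype=float)

        class _Stub:
            pass

        m = _Stub()
        m.downweight = d["downweight"]
        m.deshrink = d["deshrink"]
        m.mwmt = pd.Series(d["training_range"])
        res = cls.__new__(cls)
        res.model = m
        res.optima = optima
        res.tolerances = tolerances
        res.tolerance_floor = d["tolerance_floor"]
        res.deshrink_a = d["deshrink_a"]
        res.deshrink_b = d["deshrink_b"]
        res.raw_scores = None
        res.fittedvalues = None
        res.training_range = tuple(d["training_range"])
        return res

    def summary(self) -> str:
        perf = self.apparent_performance()
        lines = [
            "Macroinvertebrate Thermal Tolerance Index — WA calibration",
            "===========================================================",
            f"samples: {len(self.model.counts)}   OTUs: {self.optima.notna().sum()}",
            f"downweight: {self.model.downweight}   deshrink: {self.model.deshrink}",
            f"deshrink line: x0_hat = {self.deshrink_a:.4f} + {self.deshrink_b:.4f} * MWMT"
            if self.model.deshrink == "classical"
            else f"deshrink coefficients: a={self.deshrink_a:.4f}, b={self.deshrink_b:.4f}",
            f"tolerance floor: {self.tolerance_floor:.3f} degC",
            f"training MWMT range: {self.training_range[0]:.1f}-{self.training_range[1]:.1f} degC",
            "",
            "Apparent (calibration) performance",
            f"  RMSEP: {perf.rmsep:.2f} degC   R2: {perf.r2:.3f}   max bias: {perf.max_bias:.2f} degC",
        ]
        return "\n".join(lines)
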