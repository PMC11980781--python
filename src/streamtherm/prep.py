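"""Sample preparation: temperature linkage, deduplication, filtering, rollup.

Turns a validated :class:`~streamtherm.io.CommunityDataset` into the
analysis table the response-estimation stage consumes. The steps, in
pipeline order:

1. link every sample to a single MWMT value (annual model value for the
   sampling year where available, else the long-term mean, else imputed
   from mean August temperature via a Deming regression);
2. drop samples with fewer than ``min_individuals`` total organisms;
3. keep one sample per 1-km stream segment (highest richness, then most
   recent, then smallest sample id);
4. roll child-taxon abundances up into genus-or-coarser parents, and derive
   relative-abundance and presence views.

The 150-count filter is applied before deduplication by default; the order
is configurable because it affects which sample is "richest" in a segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GENUS_OR_COARSER, CommunityDataset, SampleRecord, SegmentTemperature

__all__ = [
    "DemingFit",
    "LinkedSample",
    "fit_deming",
    "link_mwmt",
    "dedupe_segments",
    "filter_min_count",
    "rollup_abundances",
    "prepare",
    "PrepResult",
]


@dataclass(frozen=True)
class DemingFit:
    """Deming (errors-in-both-variables) regression line.

    ``delta`` is the ratio of error variances (y over x); with
    ``delta = 1`` the fit minimizes perpendicular distances (major-axis /
    orthogonal regression).
    """

    slope: float
    intercept: float
    delta: float
    n: int

    def predict(self, x: float) -> float:
        return self.intercept + self.slope * x


def fit_deming(pairs, delta: float = 1.0) -> DemingFit:
    """Fit a Deming regression to ``(x, y)`` pairs.

    Closed form: with s_xx, s_yy, s_xy the (co)variances,

        slope = [s_yy - δ·s_xx + sqrt((s_yy - δ·s_xx)² + 4δ·s_xy²)] / (2·s_xy)
        intercept = ȳ - slope·x̄

    Pairs with a missing member are dropped. Raises ``ValueError`` when
    fewer than three complete pairs remain or when s_xy = 0 (slope
    undefined).
    """
    arr = np.asarray([(x, y) for x, y in pairs if x is not None and y is not None], dtype=float)
    arr = arr[np.isfinite(arr).all(axis=1)] if arr.size else arr
    if len(arr) < 3:
        raise ValueError(f"Deming regression needs >= 3 complete pairs, got {len(arr)}")
    x, y = arr[:, 0], arr[:, 1]
    sxx = np.var(x, ddof=1)
    syy = np.var(y, ddof=1)
    sxy = np.cov(x, y, ddof=1)[0, 1]
    if sxy == 0.0:
        raise ValueError("Deming slope undefined: covariance of x and y is zero")
    d = syy - delta * sxx
    slope = (d + math.sqrt(d * d + 4.0 * delta * sxy * sxy)) / (2.0 * sxy)
    intercept = float(np.mean(y) - slope * np.mean(x))
    return DemingFit(slope=float(slope), intercept=intercept, delta=delta, n=len(arr))


def fit_deming_from_dataset(dataset: CommunityDataset, delta: float = 1.0) -> DemingFit:
    """Deming fit of MWMT on mean August temperature over all segments.

    Uses the long-term mean MWMT (falling back to the mean of annual
    values) paired with mean August temperature wherever both exist.
    """
    pairs = []
    for seg in dataset.temperatures.values():
        if seg.mean_august is None:
            continue
        if seg.mean_mwmt is not None:
            pairs.append((seg.mean_august, seg.mean_mwmt))
        elif seg.annual_mwmt:
            pairs.append((seg.mean_august, float(np.mean(list(seg.annual_mwmt.values())))))
    return fit_deming(pairs, delta=delta)


@dataclass
class LinkedSample:
    """A sample joined to one MWMT value, with abundance views.

    ``rel_abund`` divides each taxon's (possibly rolled-up) count by the
    sample's total pre-rollup individuals, so fractions are comparable
    across taxonomic ranks; leaf-level fractions sum to 1.
    """

    sample_id: str
    site_id: str
    segment_id: str
    unit: str
    year: int
    mwmt: float
    mwmt_source: str  # annual | long_term_mean | imputed
    counts: dict[str, int] = field(default_factory=dict)
    rel_abund: dict[str, float] = field(default_factory=dict)
    presence: set[str] = field(default_factory=set)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    @property
    def richness(self) -> int:
        return len(self.counts)


class TemperatureLinkError(ValueError):
    """No MWMT value derivable for a sample's segment."""


def link_mwmt(
    sample: SampleRecord,
    segment_temps: dict[str, SegmentTemperature],
    deming: DemingFit | None = None,
) -> LinkedSample:
    """Attach one MWMT value to a sample.

    Priority: modeled annual value for the sampling year, then the
    long-term mean, then imputation from mean August temperature through
    the supplied Deming fit. Raises :class:`TemperatureLinkError` when
    none applies.
    """
    seg = segment_temps.get(sample.segment_id)
    if seg is None:
        raise TemperatureLinkError(
            f"sample {sample.sample_id!r}: segment {sample.segment_id!r} has no temperature record"
        )
    if sample.year in seg.annual_mwmt:
        mwmt, source = seg.annual_mwmt[sample.year], "annual"
    elif seg.mean_mwmt is not None:
        mwmt, source = seg.mean_mwmt, "long_term_mean"
    elif seg.mean_august is not None and deming is not None:
        mwmt, source = deming.predict(seg.mean_august), "imputed"
    else:
        raise TemperatureLinkError(
            f"sample {sample.sample_id!r}: no annual MWMT for {sample.year}, "
            "no long-term mean, and no Deming imputation possible"
        )
    total = sample.total_count
    rel = {t: c / total for t, c in sample.counts.items()} if total else {}
    return LinkedSample(
        sample_id=sample.sample_id,
        site_id=sample.site_id,
        segment_id=sample.segment_id,
        unit=sample.unit,
        year=sample.year,
        mwmt=float(mwmt),
        mwmt_source=source,
        counts=dict(sample.counts),
        rel_abund=rel,
        presence={t for t, c in sample.counts.items() if c >= 1},
    )


def dedupe_segments(samples):
    """Keep one sample per stream segment.

    Selection: highest total taxa richness; ties broken by most recent
    year, then lexicographically smallest sample id. Deterministic and
    independent of input order.
    """
    best: dict[str, object] = {}
    for s in samples:
        cur = best.get(s.segment_id)
        if cur is None:
            best[s.segment_id] = s
            continue
        key = (-s.richness, -s.year, s.sample_id)
        cur_key = (-cur.richness, -cur.year, cur.sample_id)
        if key < cur_key:
            best[s.segment_id] = s
    return sorted(best.values(), key=lambda s: s.sample_id)


def filter_min_count(samples, min_individuals: int = 150):
    """Drop samples with fewer than ``min_individuals`` total organisms."""
    return [s for s in samples if s.total_count >= min_individuals]


def rollup_abundances(sample, taxonomy: CommunityDataset | dict) -> dict[str, int]:
    """Aggregate child-taxon counts into genus-or-coarser parents.

    Returns effective counts: for a taxon at genus rank or coarser, its own
    count plus the summed raw counts of all its descendants present in the
    sample (the parent appears even when its own count is zero); taxa at
    sub-generic ranks keep their own counts.
    """
    taxa = taxonomy.taxa if isinstance(taxonomy, CommunityDataset) else taxonomy
    counts = sample.counts if hasattr(sample, "counts") else dict(sample)
    effective: dict[str, int] = {}
    # each observed count feeds its own taxon and every genus-or-coarser ancestor
    for taxon_id, c in counts.items():
        effective[taxon_id] = effective.get(taxon_id, 0) + c
        cur = taxa[taxon_id].parent_id
        while cur is not None:
            parent = taxa[cur]
            if parent.rank in GENUS_OR_COARSER:
                effective[cur] = effective.get(cur, 0) + c
            cur = parent.parent_id
    return effective


@dataclass
class PrepResult:
    """Outcome of the preparation pipeline."""

    samples: list[LinkedSample]
    exclusions: pd.DataFrame  # sample_id, reason
    deming: DemingFit | None

    def long_table(self, dataset: CommunityDataset) -> pd.DataFrame:
        """Tidy table of rolled-up abundances, one row per (sample, taxon).

        Columns: sample_id, mwmt, taxon_id, count (effective, rolled-up),
        rel_abund (effective count / total pre-rollup individuals),
        presence.
        """
        rows = []
        for s in self.samples:
            total = s.total_count
            eff = rollup_abundances(s, dataset)
            for t, c in eff.items():
                rows.append((s.sample_id, s.mwmt, t, c, c / total, int(c >= 1)))
        return pd.DataFrame(
            rows,
            columns=["sample_id", "mwmt", "taxon_id", "count", "rel_abund", "presence"],
        )

    def mwmt_series(self) -> pd.Series:
        return pd.Series(
            {s.sample_id: s.mwmt for s in self.samples}, name="mwmt"
        ).sort_index()


def prepare(
    dataset: CommunityDataset,
    *,
    min_individuals: int = 150,
    deming_delta: float = 1.0,
    filter_before_dedupe: bool = True,
) -> PrepResult:
    """Run the full preparation pipeline on a validated dataset."""
    try:
        deming = fit_deming_from_dataset(dataset, delta=deming_delta)
    except ValueError:
        deming = None

    linked: list[LinkedSample] = []
    exclusions: list[tuple[str, str]] = []
    for s in dataset.samples:
        try:
            linked.append(link_mwmt(s, dataset.temperatures, deming))
        except TemperatureLinkError as e:
            exclusions.append((s.sample_id, f"no_temperature: {e}"))

    def _filter(samples):
        kept = filter_min_count(samples, min_individuals)
        kept_ids = {s.sample_id for s in kept}
        for s in samples:
            if s.sample_id not in kept_ids:
                exclusions.append((s.sample_id, f"total_count_below_{min_individuals}"))
        return kept

    def _dedupe(samples):
        kept = dedupe_segments(samples)
        kept_ids = {s.sample_id for s in kept}
        for s in samples:
            if s.sample_id not in kept_ids:
                exclusions.append((s.sample_id, "duplicate_segment"))
        return kept

    if filter_before_dedupe:
        linked = _dedupe(_filter(linked))
    else:
        linked = _filter(_dedupe(linked))

    return PrepResult(
        samples=linked,
        exclusions=pd.DataFrame(exclusions, columns=["sample_id", "reason"]),
        deming=deming,
    )
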