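"""Per-sample thermal preference metrics.

For every sample, three metric types per thermal class (and per
combination group): taxa richness, percent of taxa, and percent of
individuals. Exclusion rules:

* taxa flagged for thermal variability are excluded from **all** metrics
  (numerators and denominators);
* non-distinct taxa — coarse records whose descendant is also present in
  the sample — are excluded from the richness-based metrics only;
* inconclusive/unassigned taxa belong to no class but stay in the
  denominators (they are real taxa and individuals).

The default catalog is 7 single classes x 3 metric types plus 4
combination groups x 3 = 33 metrics.
"""

from __future__ import annotations

import logging

import pandas as pd

from .rules import CATEGORIES

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_COMBOS",
    "compute_distinctness",
    "compute_metrics",
    "metrics_table",
]

#: Default combination groups (cold-side and warm-side aggregates).
DEFAULT_COMBOS: dict[str, tuple[str, ...]] = {
    "cold_steno_cold": ("cold_stenotherm", "cold"),
    "cold_steno_cold_cool": ("cold_stenotherm", "cold", "cool"),
    "warm_warm_steno": ("warm", "warm_stenotherm"),
    "warm_warm_steno_cool_warm": ("warm", "warm_stenotherm", "cool_warm"),
}


def compute_distinctness(counts: dict[str, int], dataset) -> set[str]:
    """Distinct taxa of a sample: those with no descendant present.

    A coarse record (e.g. a genus) is *non-distinct* when any of its
    descendants also occurs in the same sample; its individuals are
    ambiguous duplicates of the finer record for richness purposes.
    """
    present = set(counts)
    return {
        t for t in present
        if not (dataset.descendants(t) & present)
    }


def _metric_block(name, members, distinct_eligible, counts, cat_of,
                  rich_denom, ind_denom):
    members = set(members)
    richness = sum(1 for t in distinct_eligible if cat_of.get(t) in members)
    n_ind = sum(c for t, c in counts.items() if cat_of.get(t) in members)
    return {
        f"rich_{name}": richness,
        f"pct_taxa_{name}": 100.0 * richness / rich_denom if rich_denom else 0.0,
        f"pct_ind_{name}": 100.0 * n_ind / ind_denom if ind_denom else 0.0,
    }


def compute_metrics(
    counts: dict[str, int],
    assignments: pd.DataFrame,
    dataset,
    flagged: set[str] | None = None,
    combos: dict[str, tuple[str, ...]] | None = None,
) -> dict[str, float] | None:
    """Compute the thermal preference metric set for one sample.

    ``counts`` are the sample's raw (pre-rollup) counts. Returns ``None``
    (with a warning) when no eligible taxa remain after exclusions.
    """
    flagged = flagged or set()
    combos = DEFAULT_COMBOS if combos is None else combos
    cat_of = dict(zip(assignments["taxon_id"], assignments["category"]))

    unflagged = {t: c for t, c in counts.items() if t not in flagged}
    if not unflagged:
        logger.warning("sample has no eligible taxa after exclusions; metrics undefined")
        return None
    distinct = compute_distinctness(counts, dataset)
    distinct_eligible = {t for t in distinct if t not in flagged}

    rich_denom = len(distinct_eligible)
    ind_denom = sum(unflagged.values())
    out: dict[str, float] = {}
    for cat in CATEGORIES:
        out.update(
            _metric_block(cat, (cat,), distinct_eligible, unflagged, cat_of,
                          rich_denom, ind_denom)
        )
    for name, members in combos.items():
        out.update(
            _metric_block(name, members, distinct_eligible, unflagged, cat_of,
                          rich_denom, ind_denom)
        )
    return out


def metrics_table(
    samples,
    assignments: pd.DataFrame,
    dataset,
    flagged: set[str] | None = None,
    combos: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Metric set for every sample, one row per sample.

    ``samples`` is an iterable of linked samples (needs ``sample_id``,
    ``mwmt`` and ``counts``); the output includes MWMT for downstream
    class comparisons.
    """
    rows = []
    for s in samples:
        m = compute_metrics(s.counts, assignments, dataset, flagged=flagged, combos=combos)
        if m is None:
            continue
        rows.append({"sample_id": s.sample_id, "mwmt": s.mwmt, **m})
    return pd.DataFrame(rows)
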