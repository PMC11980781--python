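"""Thermal preference assignment rules.

Each sufficiently frequent taxon is assigned one of seven thermal
preference classes by combining its three response metrics (WA optimum,
10th/90th occurrence percentiles, GAM curve shape) against fixed numeric
rules anchored to Oregon/Washington water temperature standards. A taxon
matching several rules receives the **last** matched class in a fixed
resolution order; taxa matching none are *inconclusive*, and taxa seen in
fewer than 30 samples are not assigned at all.

Reviewer overrides (consensus expert judgment) are applied afterwards, and
parent taxa whose child taxa span more than one class are flagged as
thermally variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "CATEGORIES",
    "RESOLUTION_ORDER",
    "PreferenceRule",
    "RULES",
    "PreferenceAssignment",
    "assign_preference",
    "assign_preferences",
    "apply_overrides",
    "flag_variability",
]

#: The seven thermal preference classes, coldest to warmest niche.
CATEGORIES = (
    "cold_stenotherm",
    "cold",
    "cool",
    "cool_warm",
    "warm",
    "warm_stenotherm",
    "eurythermal",
)

#: Multi-match resolution order: a taxon matching several rules gets the
#: LAST one it matches in this sequence.
RESOLUTION_ORDER = (
    "cool_warm",
    "cool",
    "cold",
    "cold_stenotherm",
    "warm",
    "warm_stenotherm",
    "eurythermal",
)


@dataclass(frozen=True)
class PreferenceRule:
    """One row of the assignment rule table.

    Bounds are half-open conditions on the metrics; ``None`` means no
    condition. ``strict`` flags mark strict (<, >) versus non-strict
    (≤, ≥) inequalities, preserved exactly as printed in the source rule
    table — boundary values matter.
    """

    category: str
    opt_lo: float | None = None  # WA_opt > / >= opt_lo
    opt_lo_strict: bool = True
    opt_hi: float | None = None  # WA_opt < / <= opt_hi
    opt_hi_strict: bool = True
    p10_lo: float | None = None
    p10_lo_strict: bool = True
    p10_hi: float | None = None
    p10_hi_strict: bool = True
    p90_lo: float | None = None
    p90_lo_strict: bool = True
    p90_hi: float | None = None
    p90_hi_strict: bool = True
    excluded_shapes: tuple[str, ...] = ()

    def matches(self, wa_opt: float, p10: float, p90: float, shape: str) -> bool:
        def lo(v, bound, strict):
            return bound is None or (v > bound if strict else v >= bound)

        def hi(v, bound, strict):
            return bound is None or (v < bound if strict else v <= bound)

        return (
            lo(wa_opt, self.opt_lo, self.opt_lo_strict)
            and hi(wa_opt, self.opt_hi, self.opt_hi_strict)
            and lo(p10, self.p10_lo, self.p10_lo_strict)
            and hi(p10, self.p10_hi, self.p10_hi_strict)
            and lo(p90, self.p90_lo, self.p90_lo_strict)
            and hi(p90, self.p90_hi, self.p90_hi_strict)
            and shape not in self.excluded_shapes
        )


#: The seven assignment rules (°C thresholds; inequality strictness exact).
RULES: dict[str, PreferenceRule] = {
    "cold_stenotherm": PreferenceRule(
        "cold_stenotherm",
        opt_hi=16.0,
        p10_hi=12.0, p10_hi_strict=False,
        p90_hi=18.0, p90_hi_strict=False,
        excluded_shapes=("increaser", "uni_increaser"),
    ),
    "cold": PreferenceRule(
        "cold",
        opt_hi=18.0,
        p10_hi=14.0, p10_hi_strict=False,
        p90_hi=20.0, p90_hi_strict=False,
        excluded_shapes=("increaser", "uni_increaser"),
    ),
    "cool": PreferenceRule(
        "cool",
        opt_hi=20.0,
        p10_hi=16.0, p10_hi_strict=False,
        p90_hi=22.0, p90_hi_strict=False,
        excluded_shapes=("increaser", "uni_increaser"),
    ),
    "cool_warm": PreferenceRule(
        "cool_warm",
        opt_lo=17.5, opt_hi=21.5,
        p10_lo=14.0,
        p90_hi=25.0,
        excluded_shapes=("increaser", "decreaser"),
    ),
    "warm": PreferenceRule(
        "warm",
        opt_lo=19.0,
        p10_lo=14.5,
        p90_lo=23.5,
        excluded_shapes=("decreaser", "uni_decreaser"),
    ),
    "warm_stenotherm": PreferenceRule(
        "warm_stenotherm",
        opt_lo=23.0,
        p10_lo=19.0, p10_lo_strict=False,
        p90_lo=26.0, p90_lo_strict=False,
        excluded_shapes=("decreaser", "uni_decreaser"),
    ),
    "eurythermal": PreferenceRule(
        "eurythermal",
        p10_hi=14.5, p10_hi_strict=False,
        p90_lo=22.0, p90_lo_strict=False,
    ),
}


@dataclass
class PreferenceAssignment:
    """Outcome of the rule engine for one taxon."""

    taxon_id: str
    category: str  # one of CATEGORIES, or inconclusive / unassigned_low_n
    matched: tuple[str, ...]
    overridden: bool = False
    variability_flag: bool = False


def assign_preference(resp, min_occ: int = 30) -> PreferenceAssignment:
    """Assign one taxon's thermal preference from its response metrics.

    ``resp`` needs attributes ``taxon_id, n_occ, wa_optimum, p10, p90,
    shape`` (a :class:`~streamtherm.response.ThermalResponse` or any
    namespace-like object, e.g. a DataFrame row).
    """
    taxon_id = resp.taxon_id
    if resp.n_occ < min_occ:
        return PreferenceAssignment(taxon_id, "unassigned_low_n", ())
    matched = tuple(
        cat
        for cat in RESOLUTION_ORDER
        if RULES[cat].matches(resp.wa_optimum, resp.p10, resp.p90, resp.shape)
    )
    if not matched:
        return PreferenceAssignment(taxon_id, "inconclusive", ())
    return PreferenceAssignment(taxon_id, matched[-1], matched)


def assign_preferences(response_table: pd.DataFrame, min_occ: int = 30) -> pd.DataFrame:
    """Vector version over a thermal-response table.

    Returns a DataFrame with columns ``taxon_id, n_occ, wa_optimum, p10,
    p90, shape, category, matched, overridden``.
    """
    rows = []
    for r in response_table.itertuples():
        a = assign_preference(r, min_occ=min_occ)
        rows.append(
            {
                "taxon_id": r.taxon_id,
                "n_occ": r.n_occ,
                "wa_optimum": r.wa_optimum,
                "p10": r.p10,
                "p90": r.p90,
                "shape": r.shape,
                "category": a.category,
                "matched": ",".join(a.matched),
                "overridden": False,
            }
        )
    return pd.DataFrame(rows)


def apply_overrides(assignments: pd.DataFrame, overrides: dict[str, str]) -> pd.DataFrame:
    """Apply reviewer consensus overrides to an assignment table.

    Overridden taxa receive the override category with ``overridden=True``;
    overrides naming unknown taxa are skipped with a warning; override
    categories outside the seven classes raise ``ValueError``.
    """
    import logging

    bad = set(overrides.values()) - set(CATEGORIES)
    if bad:
        raise ValueError(f"override categories must be one of the seven classes, got {sorted(bad)}")
    out = assignments.copy()
    known = set(out["taxon_id"])
    for taxon_id, cat in overrides.items():
        if taxon_id not in known:
            logging.getLogger(__name__).warning(
                "override for unknown taxon %r skipped", taxon_id
            )
            continue
        mask = out["taxon_id"] == taxon_id
        out.loc[mask, "category"] = cat
        out.loc[mask, "overridden"] = True
    return out


#: Parent ranks evaluated for thermal variability.
VARIABILITY_RANKS = ("genus", "tribe", "subfamily", "family")


def flag_variability(
    assignments: pd.DataFrame,
    dataset,
    ranks: tuple[str, ...] = VARIABILITY_RANKS,
) -> pd.DataFrame:
    """Flag parent taxa whose assigned descendants span several classes.

    For every taxon at one of ``ranks`` with at least two descendant taxa
    carrying one of the seven class assignments, count descendants per
    class; the parent is flagged when they occupy two or more distinct
    classes (eurythermal counts as a class). Returns one row per evaluated
    parent with per-class child counts, mirroring a variability report.
    """
    cat_of = dict(zip(assignments["taxon_id"], assignments["category"]))
    rows = []
    for taxon_id, node in sorted(dataset.taxa.items()):
        if node.rank not in ranks:
            continue
        desc = dataset.descendants(taxon_id)
        child_cats = [cat_of[d] for d in desc if cat_of.get(d) in CATEGORIES]
        if len(child_cats) < 2:
            continue
        counts = {c: child_cats.count(c) for c in CATEGORIES}
        n_categories = sum(1 for v in counts.values() if v > 0)
        rows.append(
            {
                "parent_id": taxon_id,
                "rank": node.rank,
                "parent_category": cat_of.get(taxon_id, ""),
                **{f"n_{c}": counts[c] for c in CATEGORIES},
                "n_children": len(child_cats),
                "n_categories": n_categories,
                "flagged": n_categories >= 2,
            }
        )
    cols = [
        "parent_id", "rank", "parent_category",
        *[f"n_{c}" for c in CATEGORIES],
        "n_children", "n_categories", "flagged",
    ]
    return pd.DataFrame(rows, columns=cols)
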