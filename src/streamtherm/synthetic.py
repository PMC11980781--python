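"""Synthetic community generator for offline pipeline testing.

Emulates the statistical structure the analysis assumes without any field
data: unimodal (Gaussian) taxon abundance responses along a 4–31 °C MWMT
gradient, occupancy thinning (probability of capture below one even at
the optimum), fixed-count multinomial subsampling to ~500 individuals per
sample, a hierarchical taxonomy in which sister species diverge
thermally, and a site-temperature distribution peaked mid-gradient with
sparse extremes.

Every draw is reproducible from the scenario seed, and the generating
("truth") parameters are returned alongside the dataset so recovery can
be measured.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CommunityDataset, SampleRecord, SegmentTemperature, TaxonNode

__all__ = [
    "TaxonArchetype",
    "SyntheticScenario",
    "DEFAULT_SCENARIO",
    "generate_dataset",
    "generate_edge_cases",
]


@dataclass(frozen=True)
class TaxonArchetype:
    """Generating parameters for one taxon's thermal response."""

    taxon_id: str
    true_optimum: float  # °C
    true_tolerance: float  # °C, Gaussian response SD (> 0)
    peak_poc: float  # occupancy probability at the optimum, (0, 1]
    peak_abundance: float  # expected relative abundance weight at the optimum
    parent_id: str | None = None
    rank: str = "genus"


@dataclass(frozen=True)
class SyntheticScenario:
    """Generative scenario parameters.

    The MWMT distribution is a mixture peaked mid-gradient (normal around
    17 °C, SD 5) with a small uniform floor, truncated to ``gradient`` —
    site density thins toward both thermal extremes. Each sample is a
    fixed-count multinomial draw of ``target_total`` individuals.
    """

    n_sites: int = 300
    n_taxa: int = 60
    target_total: int = 500
    gradient: tuple[float, float] = (4.0, 31.0)
    seed: int = 42
    n_units: int = 3
    n_genus_pairs: int = 8  # genera given two thermally divergent species
    child_delta: float = 4.0  # °C optimum split between sister species
    mid: float = 17.0
    spread: float = 5.0
    uniform_mix: float = 0.15
    frac_annual: float = 0.80  # segments with an annual MWMT value
    frac_mean_only: float = 0.15  # long-term mean only; rest mean-August only
    year: int = 2015

    def __post_init__(self):
        if self.n_sites < 20:
            raise ValueError("n_sites must be >= 20")


DEFAULT_SCENARIO = SyntheticScenario()


def _draw_mwmt(rng, scenario, n):
    lo, hi = scenario.gradient
    out = np.empty(n)
    for i in range(n):
        while True:
            if rng.uniform() < scenario.uniform_mix:
                v = rng.uniform(lo, hi)
            else:
                v = rng.normal(scenario.mid, scenario.spread)
            if lo <= v <= hi:
                out[i] = v
                break
    return out


def _make_archetypes(rng, scenario) -> list[TaxonArchetype]:
    lo, hi = scenario.gradient
    n = scenario.n_taxa
    # optima spread evenly over the gradient with jitter, so cold, cool and
    # warm niches are all represented
    base = np.linspace(lo + 1.0, hi - 1.0, n) + rng.normal(0, 0.8, n)
    base = np.clip(base, lo + 0.5, hi - 0.5)
    order = rng.permutation(n)
    archetypes: list[TaxonArchetype] = []
    n_pairs = min(scenario.n_genus_pairs, n // 3)
    pair_slots = order[: n_pairs]
    for k in range(n):
        u = float(base[k])
        t = float(rng.uniform(1.5, 4.0))
        poc = float(rng.uniform(0.55, 0.95))
        amp = float(rng.lognormal(mean=2.5, sigma=0.6))
        archetypes.append(
            TaxonArchetype(f"g{k:03d}", u, t, poc, amp, parent_id=None, rank="genus")
        )
    # thermally divergent sister species under some genera
    for j, slot in enumerate(pair_slots):
        parent = archetypes[slot]
        for side, tag in ((-0.5, "a"), (+0.5, "b")):
            u = float(np.clip(parent.true_optimum + side * scenario.child_delta,
                              lo + 0.5, hi - 0.5))
            archetypes.append(
                TaxonArchetype(
                    f"{parent.taxon_id}s{tag}", u,
                    float(rng.uniform(1.2, 2.5)),
                    parent.peak_poc,
                    parent.peak_abundance * 0.6,
                    parent_id=parent.taxon_id,
                    rank="species",
                )
            )
    return archetypes


def generate_dataset(
    scenario: SyntheticScenario = DEFAULT_SCENARIO,
) -> tuple[CommunityDataset, pd.DataFrame, dict[str, str]]:
    """Draw one synthetic community dataset.

    Returns ``(dataset, truth, otu_map)``: the validated dataset, a truth
    table of generating archetype parameters, and an OTU map folding
    species into their genus and mapping every genus to itself.
    """
    rng = np.random.default_rng(scenario.seed)
    archetypes = _make_archetypes(rng, scenario)
    mwmt = _draw_mwmt(rng, scenario, scenario.n_sites)

    taxa: dict[str, TaxonNode] = {}
    n_families = 6
    for f in range(n_families):
        taxa[f"fam{f}"] = TaxonNode(f"fam{f}", f"Familidae{f}", None, "family")
    genus_idx = 0
    for a in archetypes:
        if a.parent_id is not None:
            parent = a.parent_id
        else:
            parent = f"fam{genus_idx % n_families}"
            genus_idx += 1
        taxa[a.taxon_id] = TaxonNode(a.taxon_id, a.taxon_id.upper(), parent, a.rank)

    otu_map: dict[str, str] = {}
    for a in archetypes:
        otu_map[a.taxon_id] = a.parent_id if a.parent_id is not None else a.taxon_id

    u = np.array([a.true_optimum for a in archetypes])
    t = np.array([a.true_tolerance for a in archetypes])
    poc = np.array([a.peak_poc for a in archetypes])
    amp = np.array([a.peak_abundance for a in archetypes])
    # genera with species children keep a reduced own abundance: a share of
    # individuals is only identifiable to genus level
    has_children = {a.parent_id for a in archetypes if a.parent_id}
    own_scale = np.array(
        [0.35 if a.taxon_id in has_children else 1.0 for a in archetypes]
    )

    samples: list[SampleRecord] = []
    temperatures: dict[str, SegmentTemperature] = {}
    for j in range(scenario.n_sites):
        x = mwmt[j]
        lam = amp * own_scale * np.exp(-((x - u) ** 2) / (2.0 * t**2))
        occupied = rng.uniform(size=len(archetypes)) < poc
        lam = lam * occupied
        if lam.sum() <= 0:
            lam = np.ones_like(lam)  # degenerate site: uniform filler
        counts_vec = rng.multinomial(scenario.target_total, lam / lam.sum())
        counts = {
            archetypes[k].taxon_id: int(c)
            for k, c in enumerate(counts_vec)
            if c > 0
        }
        seg_id = f"seg{j:04d}"
        sid = f"S{j:04d}"
        mode = rng.uniform()
        august = (x - 1.0) / 1.1 + rng.normal(0, 0.4)
        if mode < scenario.frac_annual:
            seg = SegmentTemperature(seg_id, annual_mwmt={scenario.year: float(x)},
                                     mean_mwmt=float(x + rng.normal(0, 0.3)),
                                     mean_august=float(august))
        elif mode < scenario.frac_annual + scenario.frac_mean_only:
            seg = SegmentTemperature(seg_id, annual_mwmt={},
                                     mean_mwmt=float(x), mean_august=float(august))
        else:
            seg = SegmentTemperature(seg_id, annual_mwmt={}, mean_mwmt=None,
                                     mean_august=float(august))
        temperatures[seg_id] = seg
        samples.append(
            SampleRecord(
                sample_id=sid, site_id=f"site{j:04d}", segment_id=seg_id,
                unit=f"unit{j % scenario.n_units}", year=scenario.year,
                counts=counts,
            )
        )

    truth = pd.DataFrame(
        [
            {
                "taxon_id": a.taxon_id,
                "true_optimum": a.true_optimum,
                "true_tolerance": a.true_tolerance,
                "peak_poc": a.peak_poc,
                "peak_abundance": a.peak_abundance,
                "parent_id": a.parent_id or "",
                "rank": a.rank,
            }
            for a in archetypes
        ]
    )
    dataset = CommunityDataset(taxa=taxa, samples=samples, temperatures=temperatures)
    return dataset, truth, otu_map


def write_scenario_csvs(scenario: SyntheticScenario, out_dir) -> dict:
    """Materialize a scenario as the three interchange CSVs plus truth/OTU map."""
    from pathlib import Path

    dataset, truth, otu_map = generate_dataset(scenario)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = pd.DataFrame(
        [
            (s.sample_id, t, c)
            for s in dataset.samples
            for t, c in sorted(s.counts.items())
        ],
        columns=["sample_id", "taxon_id", "count"],
    )
    taxonomy = pd.DataFrame(
        [
            (n.taxon_id, n.name, n.parent_id or "", n.rank)
            for n in sorted(dataset.taxa.values(), key=lambda n: n.taxon_id)
        ],
        columns=["taxon_id", "name", "parent_id", "rank"],
    )
    year = scenario.year
    sites = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "site_id": s.site_id,
                "segment_id": s.segment_id,
                "unit": s.unit,
                "year": s.year,
                f"mwmt_{year}": dataset.temperatures[s.segment_id].annual_mwmt.get(year),
                "mwmt_mean": dataset.temperatures[s.segment_id].mean_mwmt,
                "mean_august": dataset.temperatures[s.segment_id].mean_august,
            }
            for s in dataset.samples
        ]
    )
    otu = pd.DataFrame(sorted(otu_map.items()), columns=["taxon_id", "otu_id"])
    counts.to_csv(out / "counts.csv", index=False)
    taxonomy.to_csv(out / "taxonomy.csv", index=False)
    sites.to_csv(out / "sites.csv", index=False)
    truth.to_csv(out / "truth.csv", index=False)
    otu.to_csv(out / "otu_map.csv", index=False)
    return {"files": ["counts.csv", "taxonomy.csv", "sites.csv", "truth.csv", "otu_map.csv"]}


# ---------------------------------------------------------------------------
# Deterministic edge-case fixtures
# ---------------------------------------------------------------------------

def _gaussian_curve(grid, center, width, peak=0.8):
    return peak * np.exp(-((grid - center) ** 2) / (2.0 * width**2))


def generate_edge_cases() -> dict:
    """Deterministic fixtures exercising boundaries and degenerate inputs.

    Keys:

    * ``shape_curves`` — analytic POC curves with their expected shape
      category (constant, monotone ramps, centered/edge Gaussians, a
      shouldered decline);
    * ``rule_boundaries`` — taxa whose metrics sit exactly on the class
      thresholds, with the category the strict/non-strict inequality
      semantics demand;
    * ``count_trio`` — samples totaling 149/150/151 individuals around
      the low-count filter;
    * ``distinctness`` — a family→genus→species chain present together;
    * ``small_unit_split`` — a processing unit with fewer samples than
      the number of quantile bins.
    """
    from .response import GamFit

    grid = np.linspace(4.0, 31.0, 100)

    def gamfit(poc, width=0.02):
        poc = np.asarray(poc, float)
        return GamFit(grid, poc, np.clip(poc - width, 0, 1),
                      np.clip(poc + width, 0, 1), [], method="analytic")

    def _ramp(g, x0, x1, y0, y1):
        s = np.clip((g - x0) / (x1 - x0), 0.0, 1.0)
        s = 0.5 - 0.5 * np.cos(np.pi * s)
        return y0 + (y1 - y0) * s

    # gentle rise from a high cold shoulder (~60% of peak) to an interior
    # peak, then a sharp warm decline toward zero
    shoulder = np.where(
        grid <= 14.0,
        _ramp(grid, 4.0, 14.0, 0.5, 0.8),
        _ramp(grid, 14.0, 24.0, 0.8, 0.05),
    )

    shape_curves = [
        ("constant_mid", gamfit(np.full_like(grid, 0.30)), "flat"),
        ("linear_down", gamfit(np.linspace(0.6, 0.1, grid.size)), "decreaser"),
        ("linear_up", gamfit(np.linspace(0.1, 0.6, grid.size)), "increaser"),
        ("gaussian_center", gamfit(_gaussian_curve(grid, 17.5, 3.0)), "unimodal"),
        ("gaussian_cold_edge", gamfit(_gaussian_curve(grid, 4.0, 5.0)), "decreaser"),
        ("gaussian_warm_edge", gamfit(_gaussian_curve(grid, 31.0, 5.0)), "increaser"),
        ("cold_shoulder_drop", gamfit(shoulder), "uni_decreaser"),
        ("warm_shoulder_rise", gamfit(shoulder[::-1].copy()), "uni_increaser"),
        ("low_flat_noise", gamfit(0.05 + 0.04 * np.sin(grid), width=0.03), "unclear"),
    ]

    Boundary = pd.DataFrame(
        [
            # strict "< 16" optimum bound of the coldest class
            ("b_cold_steno_just_under", 15.999, 12.0, 18.0, "unimodal", 50, "cold_stenotherm"),
            ("b_cold_steno_at_16", 16.0, 12.0, 18.0, "unimodal", 50, "cold"),
            # non-strict p10 <= 12 for cold stenotherm
            ("b_p10_at_12", 15.0, 12.0, 18.0, "unimodal", 50, "cold_stenotherm"),
            ("b_p10_above_12", 15.0, 12.001, 18.0, "unimodal", 50, "cold"),
            # eurythermal needs p10 <= 14.5 AND p90 >= 22 (both non-strict)
            ("b_eury_exact", 18.0, 14.5, 22.0, "flat", 50, "eurythermal"),
            ("b_eury_p90_short", 22.0, 16.0, 23.0, "unimodal", 50, "inconclusive"),
            # warm requires p90 > 23.5 strictly; at the boundary only the
            # overlapping cool_warm rule still matches
            ("b_warm_p90_at_235", 21.0, 15.0, 23.5, "unimodal", 50, "cool_warm"),
            ("b_warm_p90_above", 21.0, 15.0, 23.501, "unimodal", 50, "warm"),
            # multi-match: cool+cold+cold_steno resolve to cold_stenotherm
            ("b_multimatch_cold", 14.0, 10.0, 17.0, "uni_decreaser", 50, "cold_stenotherm"),
            # low occurrence short-circuits everything
            ("b_low_n", 14.0, 10.0, 17.0, "uni_decreaser", 29, "unassigned_low_n"),
        ],
        columns=["taxon_id", "wa_optimum", "p10", "p90", "shape", "n_occ", "expected"],
    )

    count_trio = {"c149": 149, "c150": 150, "c151": 151}

    taxa = {
        "famX": TaxonNode("famX", "FamX", None, "family"),
        "genX": TaxonNode("genX", "GenX", "famX", "genus"),
        "spX": TaxonNode("spX", "SpX", "genX", "species"),
        "genY": TaxonNode("genY", "GenY", "famX", "genus"),
    }
    distinct_dataset = CommunityDataset(taxa=taxa, samples=[], temperatures={})
    distinct_counts = {"famX": 3, "genX": 10, "spX": 5, "genY": 2}
    distinct_expected = {"spX", "genY"}

    rng_units = {"unitA": 40, "unitB": 3}  # unitB smaller than 5 bins

    return {
        "shape_curves": shape_curves,
        "rule_boundaries": Boundary,
        "count_trio": count_trio,
        "distinctness": (distinct_dataset, distinct_counts, distinct_expected),
        "small_unit_split": rng_units,
    }
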