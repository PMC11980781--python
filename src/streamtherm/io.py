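"""Community dataset container and CSV interchange I/O.

The dataset bundles three pieces that the rest of the pipeline consumes:

* a taxonomy forest (:class:`TaxonNode`),
* per-sample macroinvertebrate counts (:class:`SampleRecord`), and
* modeled stream temperatures per 1-km stream segment
  (:class:`SegmentTemperature`).

The on-disk interchange formats are plain CSV:

``counts.csv``
    ``sample_id,taxon_id,count`` — long (tidy) layout, one row per taxon
    observed in a sample.
``taxonomy.csv``
    ``taxon_id,name,parent_id,rank`` with ``rank`` one of
    :data:`RANK_ORDER` and ``parent_id`` empty for roots.
``sites.csv``
    ``sample_id,site_id,segment_id,unit,year`` plus optional
    ``mwmt_<year>`` columns, ``mwmt_mean`` and ``mean_august``.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "RANK_ORDER",
    "TaxonNode",
    "SampleRecord",
    "SegmentTemperature",
    "CommunityDataset",
    "ValidationError",
    "read_dataset",
    "write_results",
]

#: Taxonomic ranks from finest to coarsest. Child ranks must be strictly
#: finer than their parents'.
RANK_ORDER = (
    "species",
    "species_group",
    "subgenus",
    "genus",
    "tribe",
    "subfamily",
    "family",
    "coarser",
)

#: Ranks at which child abundances are rolled up into the parent record.
GENUS_OR_COARSER = frozenset(RANK_ORDER[RANK_ORDER.index("genus"):])

_TEMP_RANGE = (-1.0, 45.0)


class ValidationError(ValueError):
    """Raised when an input dataset violates a structural invariant."""


@dataclass(frozen=True)
class TaxonNode:
    """One node of the taxonomy forest."""

    taxon_id: str
    name: str
    parent_id: str | None
    rank: str

    def __post_init__(self) -> None:
        if self.rank not in RANK_ORDER:
            raise ValidationError(
                f"taxon {self.taxon_id!r}: unknown rank {self.rank!r}"
            )


@dataclass
class SampleRecord:
    """One macroinvertebrate sample with its raw counts."""

    sample_id: str
    site_id: str
    segment_id: str
    unit: str
    year: int
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    @property
    def richness(self) -> int:
        return len(self.counts)


@dataclass
class SegmentTemperature:
    """Modeled temperatures for one 1-km stream segment (°C).

    ``annual_mwmt`` maps sampling year to the maximum weekly maximum
    temperature modeled for that year; ``mean_mwmt`` is the long-term
    (multi-year) average MWMT and ``mean_august`` the mean August
    temperature, either of which may be missing.
    """

    segment_id: str
    annual_mwmt: dict[int, float] = field(default_factory=dict)
    mean_mwmt: float | None = None
    mean_august: float | None = None


@dataclass
class CommunityDataset:
    """Validated bundle of taxonomy, samples and segment temperatures."""

    taxa: dict[str, TaxonNode]
    samples: list[SampleRecord]
    temperatures: dict[str, SegmentTemperature]

    def __post_init__(self) -> None:
        self.validate()

    # -- structural checks -------------------------------------------------

    def validate(self) -> None:
        _check_taxonomy(self.taxa)
        unknown: set[str] = set()
        for s in self.samples:
            for t, c in s.counts.items():
                if t not in self.taxa:
                    unknown.add(t)
                if c < 1:
                    raise ValidationError(
                        f"sample {s.sample_id!r}: count for {t!r} is {c}; "
                        "listed taxa must have count >= 1"
                    )
        if unknown:
            raise ValidationError(
                "counts reference unknown taxon ids: "
                + ", ".join(sorted(unknown))
            )
        for seg in self.temperatures.values():
            for val in [*seg.annual_mwmt.values(), seg.mean_mwmt, seg.mean_august]:
                if val is None:
                    continue
                if not (_TEMP_RANGE[0] <= val <= _TEMP_RANGE[1]):
                    raise ValidationError(
                        f"segment {seg.segment_id!r}: temperature {val} °C "
                        f"outside plausible range {_TEMP_RANGE}"
                    )

    def children(self, taxon_id: str) -> list[str]:
        return [t.taxon_id for t in self.taxa.values() if t.parent_id == taxon_id]

    def descendants(self, taxon_id: str) -> set[str]:
        """All strict descendants of ``taxon_id`` in the forest."""
        out: set[str] = set()
        stack = self.children(taxon_id)
        while stack:
            t = stack.pop()
            out.add(t)
            stack.extend(self.children(t))
        return out


def _check_taxonomy(taxa: dict[str, TaxonNode]) -> None:
    for node in taxa.values():
        if node.parent_id is not None and node.parent_id not in taxa:
            raise ValidationError(
                f"taxon {node.taxon_id!r}: parent {node.parent_id!r} not in taxonomy"
            )
    # cycle detection by walking parent chains
    for node in taxa.values():
        seen = [node.taxon_id]
        cur = node.parent_id
        while cur is not None:
            if cur in seen:
                cycle = seen[seen.index(cur):] + [cur]
                raise ValidationError(
                    "taxonomy parent links contain a cycle: " + " -> ".join(cycle)
                )
            seen.append(cur)
            cur = taxa[cur].parent_id
    # child rank strictly finer than ancestor rank
    order = {r: i for i, r in enumerate(RANK_ORDER)}
    for node in taxa.values():
        if node.parent_id is not None:
            parent = taxa[node.parent_id]
            if order[node.rank] >= order[parent.rank]:
                raise ValidationError(
                    f"taxon {node.taxon_id!r} ({node.rank}) is not finer than "
                    f"its parent {parent.taxon_id!r} ({parent.rank})"
                )


# -- readers ---------------------------------------------------------------

def read_dataset(
    counts_path: str | Path,
    taxonomy_path: str | Path,
    sites_path: str | Path,
) -> CommunityDataset:
    """Read and validate the three interchange CSVs into a dataset.

    Duplicate ``(sample_id, taxon_id)`` rows in the counts table are an
    error rather than being silently summed; unresolvable taxon or segment
    references raise :class:`ValidationError` naming the offenders.
    """
    counts = pd.read_csv(counts_path, dtype={"sample_id": str, "taxon_id": str})
    taxonomy = pd.read_csv(
        taxonomy_path, dtype={"taxon_id": str, "parent_id": str, "name": str}
    )
    sites = pd.read_csv(
        sites_path,
        dtype={"sample_id": str, "site_id": str, "segment_id": str, "unit": str},
    )

    dup = counts.duplicated(subset=["sample_id", "taxon_id"], keep=False)
    if dup.any():
        pairs = counts.loc[dup, ["sample_id", "taxon_id"]].drop_duplicates()
        raise ValidationError(
            "duplicate (sample_id, taxon_id) rows in counts: "
            + "; ".join(f"({r.sample_id}, {r.taxon_id})" for r in pairs.itertuples())
        )

    taxa = {
        str(r.taxon_id): TaxonNode(
            taxon_id=str(r.taxon_id),
            name=str(r.name),
            parent_id=None if pd.isna(r.parent_id) or r.parent_id == "" else str(r.parent_id),
            rank=str(r.rank),
        )
        for r in taxonomy.itertuples()
    }

    annual_cols = {
        c: int(m.group(1))
        for c in sites.columns
        if (m := re.fullmatch(r"mwmt_(\d{4})", c))
    }
    temperatures: dict[str, SegmentTemperature] = {}
    samples: list[SampleRecord] = []
    by_sample = {
        sid: dict(zip(g["taxon_id"], g["count"].astype(int)))
        for sid, g in counts.groupby("sample_id")
    }
    for r in sites.itertuples():
        seg_id = str(r.segment_id)
        if seg_id not in temperatures:
            annual = {}
            for col, yr in annual_cols.items():
                v = getattr(r, col)
                if pd.notna(v):
                    annual[yr] = float(v)
            mean_mwmt = getattr(r, "mwmt_mean", None)
            mean_aug = getattr(r, "mean_august", None)
            temperatures[seg_id] = SegmentTemperature(
                segment_id=seg_id,
                annual_mwmt=annual,
                mean_mwmt=None if mean_mwmt is None or pd.isna(mean_mwmt) else float(mean_mwmt),
                mean_august=None if mean_aug is None or pd.isna(mean_aug) else float(mean_aug),
            )
        samples.append(
            SampleRecord(
                sample_id=str(r.sample_id),
                site_id=str(r.site_id),
                segment_id=seg_id,
                unit=str(r.unit),
                year=int(r.year),
                counts=by_sample.get(str(r.sample_id), {}),
            )
        )

    known_samples = {s.sample_id for s in samples}
    orphans = sorted(set(by_sample) - known_samples)
    if orphans:
        raise ValidationError(
            "counts reference sample ids missing from sites: " + ", ".join(orphans)
        )
    return CommunityDataset(taxa=taxa, samples=samples, temperatures=temperatures)


# -- writers ---------------------------------------------------------------

_SORT_KEYS = ("taxon_id", "sample_id", "otu_id", "parent_id", "segment_id")


def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    *,
    seed: int | None = None,
    config: dict | None = None,
) -> dict:
    """Write result tables as CSV with a sidecar JSON manifest.

    Rows are sorted by the first identifier column present (taxon_id,
    sample_id, ...) and columns keep their given order, so repeated runs
    produce byte-identical files. Returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from . import __version__

    files = []
    for name, df in tables.items():
        df = df.copy()
        sort_cols = [c for c in _SORT_KEYS if c in df.columns]
        if sort_cols:
            df = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
        path = out / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.12g")
        files.append(path.name)
    cfg = config or {}
    manifest = {
        "tool": "streamtherm",
        "version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest()[:16],
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
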