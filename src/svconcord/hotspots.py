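"""SV-hotspot annotation and per-sample burden counts.

Hotspots are published genomic regions recurrently rearranged across a
myeloma cohort, each categorized as gain, loss or fragile. An SV "hits"
a hotspot when at least one of its breakpoints — an interval endpoint,
or either breakend of a translocation — falls inside the hotspot region
(breakpoint-containment semantics; whole-interval overlap is available
as an alternative). Each hotspot counts once per sample no matter how
many calls support it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Optional

import pandas as pd

from svconcord.io import GenomicInterval, SVCallset

HOTSPOT_CATEGORIES = ("gain", "loss", "fragile")


@dataclass(frozen=True)
class HotspotEntry:
    hotspot_id: str
    region: GenomicInterval
    category: str

    def __post_init__(self) -> None:
        if self.category not in HOTSPOT_CATEGORIES:
            raise ValueError(f"unknown hotspot category {self.category!r}")


@dataclass(frozen=True)
class HotspotCatalog:
    """A catalog of hotspot regions with unique ids."""

    entries: tuple

    def __post_init__(self) -> None:
        ids = [e.hotspot_id for e in self.entries]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate hotspot ids: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def category_counts(self) -> dict:
        counts = {c: 0 for c in HOTSPOT_CATEGORIES}
        for e in self.entries:
            counts[e.category] += 1
        return counts


@dataclass
class HotspotHits:
    """Hotspots hit in one sample, with the supporting call ids per hotspot."""

    sample: str
    method: str
    # hotspot_id -> {"category": str, "record_ids": sorted list}
    hits: dict = field(default_factory=dict)

    def add(self, entry: HotspotEntry, record_id: str) -> None:
        slot = self.hits.setdefault(
            entry.hotspot_id, {"category": entry.category, "record_ids": []}
        )
        if record_id not in slot["record_ids"]:
            slot["record_ids"].append(record_id)
            slot["record_ids"].sort()

    def hotspot_ids(self) -> set:
        return set(self.hits)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample": self.sample,
                "hotspot_id": hid,
                "category": info["category"],
                "n_supporting": len(info["record_ids"]),
                "record_ids": ",".join(info["record_ids"]),
            }
            for hid, info in sorted(self.hits.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["sample", "hotspot_id", "category", "n_supporting", "record_ids"],
        )


def _breakpoints(rec) -> list:
    """The breakpoint positions of a record: interval endpoints or the breakend."""
    if rec.svtype == "BND":
        return [(rec.breakend.chrom, rec.breakend.pos)]
    iv = rec.interval
    return [(iv.chrom, iv.start), (iv.chrom, iv.end - 1)]


def annotate_hotspots(
    callset: SVCallset,
    catalog: HotspotCatalog,
    pass_only: bool = True,
    mode: str = "breakpoint",
) -> HotspotHits:
    """Identify catalog hotspots hit by a callset's SV calls.

    mode="breakpoint" (default): a call supports a hotspot when any of
    its breakpoints lies inside the region — robust for large SVs that
    span many hotspots. mode="overlap": any interval overlap counts
    (translocations still match by breakend containment). Only calls
    passing the caller's quality filters contribute by default.
    """
    if mode not in ("breakpoint", "overlap"):
        raise ValueError(f"unknown hit mode {mode!r}")
    cs = callset.filtered(pass_only)
    hits = HotspotHits(sample=cs.sample, method=cs.method)

    for entry in catalog:
        region = entry.region
        for rec in cs.records:
            if rec.svtype == "BND":
                continue  # handled via assembled events / unpaired breakends below
            if mode == "overlap":
                hit = rec.interval.overlaps(region)
            else:
                hit = any(region.contains(c, p) for c, p in _breakpoints(rec))
            if hit:
                hits.add(entry, rec.record_id)
        for ev in cs.translocations:
            if region.contains(ev.breakend_a.chrom, ev.breakend_a.pos) or region.contains(
                ev.breakend_b.chrom, ev.breakend_b.pos
            ):
                hits.add(entry, "|".join(ev.source_ids))
        for rec in cs.unpaired_bnds:
            if region.contains(rec.breakend.chrom, rec.breakend.pos):
                hits.add(entry, rec.record_id)
    return hits


def hotspot_counts(hits: HotspotHits) -> dict:
    """Total and per-category hotspot counts (and proportions) for one sample.

    Each hotspot counts once regardless of how many calls support it.
    Proportions sum to 1 when the total is positive.
    """
    counts = {c: 0 for c in HOTSPOT_CATEGORIES}
    for info in hits.hits.values():
        counts[info["category"]] += 1
    total = sum(counts.values())
    proportions = {
        c: (counts[c] / total if total else 0.0) for c in HOTSPOT_CATEGORIES
    }
    return {"total": total, "counts": counts, "proportions": proportions}


def cohort_summary(per_sample_totals: Iterable[int]) -> dict:
    """Cohort-level burden summary: median (midpoint for even n) and mean."""
    totals = list(per_sample_totals)
    if not totals:
        raise ValueError("cohort is empty: no per-sample hotspot counts")
    return {
        "n_samples": len(totals),
        "median": float(median(totals)),
        "mean": sum(totals) / len(totals),
    }
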