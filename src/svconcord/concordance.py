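"""Type-stratified concordance between two SV callsets.

Interval-type calls (DEL, DUP, INV) match under the reciprocal-overlap
rule: two same-type intervals agree when their shared span is at least a
fraction F (default 0.70) of *both* interval lengths. Insertions are
matched by insertion-point proximity, since span overlap is undefined
for point events. Translocations — which have no end position — are
compared separately by chromosome pair and per-breakend distance.

"Shared" counts unique A-side features with at least one qualifying
match in B (directional semantics: a single A feature matching several B
features still counts once).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
from intervaltree import IntervalTree

from svconcord.io import GenomicInterval, SVCallset, SV_TYPES, TranslocationEvent

INTERVAL_TYPES = ("DEL", "DUP", "INS", "INV")


@dataclass(frozen=True)
class MatchConfig:
    """Matching parameters for callset comparison.

    fraction : reciprocal-overlap threshold F in (0, 1].
    reciprocal : require the fraction on both intervals (bedtools -f F -r)
        rather than on the A interval alone (-f F).
    translocation_window : per-breakend tolerance in bp for translocation
        matching.
    ins_window : insertion-point proximity tolerance in bp.
    require_same_type : stratify matching by SV type.
    """

    fraction: float = 0.70
    reciprocal: bool = True
    translocation_window: int = 10_000
    ins_window: int = 50
    require_same_type: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must lie in (0, 1]")
        if self.translocation_window < 0:
            raise ValueError("translocation_window must be >= 0")


@dataclass
class ConcordanceTable:
    """Per-type shared / A-only / B-only counts between two callsets."""

    method_a: str
    method_b: str
    counts: dict = field(default_factory=dict)  # svtype -> dict of counts

    def add(self, svtype: str, n_a: int, n_b: int, shared: int, shared_b: int) -> None:
        self.counts[svtype] = {
            "n_a": n_a,
            "n_b": n_b,
            "shared": shared,  # unique A features with >=1 B match
            "a_only": n_a - shared,
            "b_only": n_b - shared_b,
            "shared_b": shared_b,  # unique B features with >=1 A match
        }

    def __getitem__(self, svtype: str) -> dict:
        return self.counts[svtype]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for svtype, c in self.counts.items():
            rows.append({"method_a": self.method_a, "method_b": self.method_b,
                         "svtype": svtype, **c})
        return pd.DataFrame(rows)


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> tuple:
    """Overlap of two intervals as fractions of each: (|a∩b|/|a|, |a∩b|/|b|).

    Different chromosomes give (0.0, 0.0). Swapping the arguments swaps
    the components.
    """
    shared = a.overlap_length(b)
    if shared == 0:
        return 0.0, 0.0
    return shared / len(a), shared / len(b)


def _interval_match(a: GenomicInterval, b: GenomicInterval, cfg: MatchConfig) -> bool:
    fa, fb = reciprocal_overlap(a, b)
    if cfg.reciprocal:
        return fa >= cfg.fraction and fb >= cfg.fraction
    return fa >= cfg.fraction


def _ins_match(a: GenomicInterval, b: GenomicInterval, cfg: MatchConfig) -> bool:
    return a.chrom == b.chrom and abs(a.start - b.start) <= cfg.ins_window


def match_callsets(
    a: SVCallset,
    b: SVCallset,
    cfg: Optional[MatchConfig] = None,
    allow_sample_mismatch: bool = False,
) -> ConcordanceTable:
    """Compare two callsets type by type under the reciprocal-overlap rule.

    BND records and translocation events are excluded here; route them
    through :func:`match_translocations`, which handles the missing end
    position. Both callsets must come from the same sample unless
    ``allow_sample_mismatch`` is set.
    """
    cfg = cfg or MatchConfig()
    if a.sample != b.sample and not allow_sample_mismatch:
        raise ValueError(
            f"callsets come from different samples ({a.sample!r} vs {b.sample!r}); "
            "pass allow_sample_mismatch=True to compare anyway"
        )
    table = ConcordanceTable(method_a=a.method, method_b=b.method)
    for svtype in INTERVAL_TYPES:
        recs_a = a.interval_records(svtype)
        recs_b = b.interval_records(svtype)
        matcher = _ins_match if svtype == "INS" else _interval_match
        shared_a = _count_matched(recs_a, recs_b, matcher, cfg)
        shared_b = _count_matched(recs_b, recs_a, _flip(matcher), cfg)
        table.add(svtype, len(recs_a), len(recs_b), shared_a, shared_b)
    return table


def _flip(matcher):
    return lambda x, y, cfg: matcher(y, x, cfg)


def _count_matched(recs_query, recs_subject, matcher, cfg: MatchConfig) -> int:
    """Unique query features with >=1 qualifying subject match (tree-indexed)."""
    trees = {}
    for rec in recs_subject:
        iv = rec.interval
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start - cfg.ins_window,
                                                        iv.end + cfg.ins_window, iv)
    matched = 0
    for rec in recs_query:
        iv = rec.interval
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            if matcher(iv, hit.data, cfg):
                matched += 1
                break
    return matched


def translocation_match(
    a: TranslocationEvent, b: TranslocationEvent, window: int
) -> bool:
    """Two translocation events match when their chromosome pairs agree and
    each corresponding breakend lies within ``window`` bp.

    Breakend correspondence is chosen to minimize the maximum
    displacement (relevant when both breakends share a chromosome).
    """
    if a.chrom_pair != b.chrom_pair:
        return False
    pairings = []
    for x, y in ((a.breakend_a, a.breakend_b), (a.breakend_b, a.breakend_a)):
        if x.chrom == b.breakend_a.chrom and y.chrom == b.breakend_b.chrom:
            pairings.append(max(abs(x.pos - b.breakend_a.pos), abs(y.pos - b.breakend_b.pos)))
    return bool(pairings) and min(pairings) <= window


def match_translocations(
    a: SVCallset,
    b: SVCallset,
    cfg: Optional[MatchConfig] = None,
) -> dict:
    """Directional translocation concordance counts.

    Returns ``{"n_a", "n_b", "shared", "a_only", "b_only"}`` where
    shared counts unique A events with >=1 qualifying B match.
    """
    cfg = cfg or MatchConfig()
    w = cfg.translocation_window
    events_a, events_b = a.translocations, b.translocations
    shared = sum(
        1 for ea in events_a if any(translocation_match(ea, eb, w) for eb in events_b)
    )
    shared_b = sum(
        1 for eb in events_b if any(translocation_match(ea, eb, w) for ea in events_a)
    )
    return {
        "n_a": len(events_a),
        "n_b": len(events_b),
        "shared": shared,
        "a_only": len(events_a) - shared,
        "b_only": len(events_b) - shared_b,
    }


def type_composition(callset: SVCallset) -> dict:
    """Proportion of calls per SV type (translocation adjacencies count once).

    Proportions sum to 1 within floating-point tolerance. An empty
    callset has no composition and raises.
    """
    counts = callset.type_counts()
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"callset {callset.sample}/{callset.method} has no calls")
    return {t: counts[t] / total for t in SV_TYPES}
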