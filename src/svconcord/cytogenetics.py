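"""Detection of the ten routinely assayed multiple-myeloma cytogenetic events.

The clinical panel comprises four arm-level losses — del(1p), del(13q),
del(14q), del(17p) — one arm-level gain, gain(1q), and the five
recurrent IGH translocations t(4;14), t(6;14), t(11;14), t(14;16) and
t(14;20). Arm events are supported by deletion/duplication calls
overlapping the arm interval; translocations by assembled breakend pairs
joining the two chromosomes. Support scores are call counts, giving each
(sample, event) cell a non-negative integer usable as a ROC score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from svconcord.io import ArmDefinition, GenomicInterval, SVCallset

ARM_EVENT_DEFS = (
    ("del(1p)", "arm_loss", "1", "p"),
    ("gain(1q)", "arm_gain", "1", "q"),
    ("del(13q)", "arm_loss", "13", "q"),
    ("del(14q)", "arm_loss", "14", "q"),
    ("del(17p)", "arm_loss", "17", "p"),
)

IGH_PARTNERS = ("4", "6", "11", "16", "20")

#: SV type supporting each arm-event kind.
_KIND_SVTYPE = {"arm_loss": "DEL", "arm_gain": "DUP"}


@dataclass(frozen=True)
class CytoEventSpec:
    """One panel event: an arm-level gain/loss or a recurrent translocation."""

    event_id: str
    kind: str  # arm_loss | arm_gain | translocation
    region: Optional[GenomicInterval] = None
    chrom_pair: Optional[tuple] = None
    min_sv_size: int = 0

    def __post_init__(self) -> None:
        if self.kind in ("arm_loss", "arm_gain"):
            if self.region is None:
                raise ValueError(f"arm event {self.event_id} needs a region")
        elif self.kind == "translocation":
            if self.chrom_pair is None:
                raise ValueError(f"translocation event {self.event_id} needs a chrom_pair")
        else:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass(frozen=True)
class PredictionMatrix:
    """Per-sample, per-event SV support scores (non-negative call counts)."""

    table: pd.DataFrame  # index: samples, columns: event ids, int cells
    method: str = ""

    @property
    def samples(self) -> list:
        return list(self.table.index)

    @property
    def events(self) -> list:
        return list(self.table.columns)

    def score(self, sample: str, event_id: str) -> int:
        return int(self.table.at[sample, event_id])


def build_event_panel(
    arms: ArmDefinition, min_sv_size: int = 0
) -> list:
    """Construct the ten-event clinical panel from an arm map.

    Requires arm intervals for chromosomes 1, 13, 14 and 17. The five
    translocation events pair chromosome 14 (IGH locus) with 4, 6, 11,
    16 and 20 at chromosome-pair granularity.
    """
    panel = []
    for event_id, kind, chrom, arm in ARM_EVENT_DEFS:
        region = arms.get(chrom, arm)
        if region is None:
            raise ValueError(f"arm map lacks {chrom}{arm}, needed for {event_id}")
        panel.append(
            CytoEventSpec(event_id=event_id, kind=kind, region=region,
                          min_sv_size=min_sv_size)
        )
    for partner in IGH_PARTNERS:
        low, high = sorted((14, int(partner)))
        panel.append(
            CytoEventSpec(event_id=f"t({low};{high})", kind="translocation",
                          chrom_pair=tuple(sorted(("14", partner))))
        )
    return panel


def detect_events(
    callset: SVCallset,
    panel: Iterable[CytoEventSpec],
    pass_only: bool = True,
) -> dict:
    """Score every panel event for one callset.

    Arm-loss scores count DEL calls overlapping the arm region by at
    least 1 bp (and at least ``min_sv_size`` long); arm gains count DUP
    calls likewise; translocation scores count assembled breakend pairs
    joining the event's chromosome pair. Only calls passing the caller's
    quality filters contribute by default. Breakends must be paired
    before scoring (unpaired BNDs never support a translocation event).
    """
    cs = callset.filtered(pass_only)
    panel = list(panel)
    chroms_needed = set()
    for spec in panel:
        if spec.region is not None:
            chroms_needed.add(spec.region.chrom)
        if spec.chrom_pair is not None:
            chroms_needed.update(spec.chrom_pair)
    chroms_seen = {r.interval.chrom for r in cs.records if r.interval is not None}
    chroms_seen |= {r.breakend.chrom for r in cs.records if r.breakend is not None}
    chroms_seen |= {b for t in cs.translocations for b in t.chrom_pair}
    if cs.records and not (chroms_needed & chroms_seen):
        warnings.warn(
            f"callset {cs.sample}/{cs.method} shares no chromosomes with the panel; "
            "all scores will be zero",
            stacklevel=2,
        )

    row = {}
    for spec in panel:
        if spec.kind == "translocation":
            score = sum(
                1
                for ev in cs.translocations
                if ev.is_interchromosomal and ev.chrom_pair == spec.chrom_pair
            )
        else:
            svtype = _KIND_SVTYPE[spec.kind]
            score = sum(
                1
                for rec in cs.interval_records(svtype)
                if rec.interval.overlaps(spec.region)
                and _record_size(rec) >= spec.min_sv_size
            )
        row[spec.event_id] = score
    return row


def _record_size(rec) -> int:
    return abs(rec.svlen) if rec.svlen is not None else len(rec.interval)


def build_prediction_matrix(
    callsets: Iterable[SVCallset],
    panel: Iterable[CytoEventSpec],
    pass_only: bool = True,
) -> dict:
    """Score a cohort of callsets, one prediction matrix per method.

    Returns ``{method: PredictionMatrix}``. Each (sample, method) must
    appear at most once.
    """
    panel = list(panel)
    callsets = list(callsets)
    if not callsets:
        raise ValueError("no callsets supplied")
    seen = set()
    rows_by_method = {}
    for cs in callsets:
        key = (cs.sample, cs.method)
        if key in seen:
            raise ValueError(f"duplicate callset for sample={cs.sample!r}, method={cs.method!r}")
        seen.add(key)
        rows_by_method.setdefault(cs.method, {})[cs.sample] = detect_events(
            cs, panel, pass_only=pass_only
        )
    event_ids = [spec.event_id for spec in panel]
    return {
        method: PredictionMatrix(
            table=pd.DataFrame.from_dict(rows, orient="index")[event_ids].astype(int),
            method=method,
        )
        for method, rows in rows_by_method.items()
    }
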