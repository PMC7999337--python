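"""Readers, writers and domain types for SV callsets and companion tables.

All genomic coordinates are held internally as 0-based half-open
intervals. VCF input (1-based, END inclusive) is converted at the I/O
boundary and nowhere else, so downstream overlap arithmetic never has to
reason about conventions. Chromosome-name dialects ("chr1" vs "1") are
normalized by a configurable prefix policy, default: strip the "chr"
prefix.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
from cyvcf2 import VCF

SV_TYPES = ("DEL", "DUP", "INS", "INV", "BND")

#: Records shorter than this many bp fall below the conventional SV size
#: definition; the candidate callsets retain them, flagged.
SV_MIN_SIZE = 50


class SVFormatError(ValueError):
    """Raised when an input file violates the expected format."""


def normalize_chrom(name: str, policy: str = "strip") -> str:
    """Normalize a chromosome name according to a prefix policy.

    policy="strip" removes a leading "chr"; policy="add" ensures one;
    policy="keep" returns the name unchanged.
    """
    if not name:
        raise SVFormatError("empty chromosome name")
    if policy == "strip":
        return name[3:] if name.lower().startswith("chr") else name
    if policy == "add":
        return name if name.lower().startswith("chr") else "chr" + name
    if policy == "keep":
        return name
    raise ValueError(f"unknown chromosome-name policy: {policy!r}")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(
                f"interval start must precede end: {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap_length(other) > 0

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


class BndOrientation(str, Enum):
    """The four VCF breakend bracket classes.

    The names describe the local junction: which side of the local base
    the partner sequence attaches to, and whether the partner segment
    extends rightwards (``[p[`` style) or leftwards (``]p]`` style) of
    the mate position.
    """

    T_RIGHT_FWD = "t[p["  # piece right of mate joins after local base
    T_LEFT_REV = "t]p]"  # reverse-complemented piece left of mate joins after
    LEFT_FWD = "]p]t"  # piece left of mate joins before local base
    RIGHT_REV = "[p[t"  # reverse-complemented piece right of mate joins before


@dataclass(frozen=True)
class Breakend:
    """One side of a breakend adjacency (0-based position)."""

    chrom: str
    pos: int
    orientation: BndOrientation


@dataclass(frozen=True)
class SVRecord:
    """A single normalized SV call.

    Non-BND records carry ``interval``; BND records carry ``breakend``
    (their own side of the adjacency) plus the mate coordinate parsed
    from the ALT bracket notation and, when present, the MATEID link.
    """

    record_id: str
    sample: str
    method: str
    svtype: str
    interval: Optional[GenomicInterval] = None
    svlen: Optional[int] = None
    quality: Optional[float] = None
    filters: frozenset = frozenset()
    mate_id: Optional[str] = None
    breakend: Optional[Breakend] = None
    mate_breakend: Optional[Breakend] = None

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown SVTYPE {self.svtype!r} in record {self.record_id}")
        if self.svtype == "BND":
            if self.breakend is None:
                raise ValueError(f"BND record {self.record_id} lacks a breakend")
        elif self.interval is None:
            raise ValueError(f"{self.svtype} record {self.record_id} lacks an interval")

    @property
    def is_sub50(self) -> bool:
        """True when the record's known length falls below the 50 bp SV floor."""
        return self.svlen is not None and abs(self.svlen) < SV_MIN_SIZE

    @property
    def is_pass(self) -> bool:
        """True when the caller applied no failing filter (PASS or unfiltered)."""
        return self.filters <= {"PASS", "."}


@dataclass(frozen=True)
class TranslocationEvent:
    """An assembled breakend pair (one adjacency, two source records)."""

    breakend_a: Breakend
    breakend_b: Breakend
    source_ids: tuple
    filters: frozenset = frozenset()
    quality: Optional[float] = None

    @property
    def chrom_pair(self) -> tuple:
        """Unordered (canonically sorted) chromosome pair."""
        return tuple(sorted((self.breakend_a.chrom, self.breakend_b.chrom)))

    @property
    def is_interchromosomal(self) -> bool:
        return self.breakend_a.chrom != self.breakend_b.chrom

    @property
    def is_pass(self) -> bool:
        return self.filters <= {"PASS", "."}


@dataclass
class SVCallset:
    """All SV calls for one (sample, method).

    ``records`` holds every parsed record, BNDs included. After
    ``pair_breakends`` each BND record belongs to exactly one
    ``TranslocationEvent`` or sits in ``unpaired_bnds``; a freshly read
    callset has every BND in ``unpaired_bnds``.
    """

    sample: str
    method: str
    records: list = field(default_factory=list)
    translocations: list = field(default_factory=list)
    unpaired_bnds: list = field(default_factory=list)

    def interval_records(self, svtype: Optional[str] = None) -> list:
        recs = [r for r in self.records if r.svtype != "BND"]
        if svtype is not None:
            recs = [r for r in recs if r.svtype == svtype]
        return recs

    def type_counts(self) -> dict:
        """Calls per type; a translocation event or unpaired BND counts once."""
        counts = {t: 0 for t in SV_TYPES}
        for rec in self.records:
            if rec.svtype != "BND":
                counts[rec.svtype] += 1
        counts["BND"] = len(self.translocations) + len(self.unpaired_bnds)
        return counts

    def n_calls(self) -> int:
        return sum(self.type_counts().values())

    def filtered(self, pass_only: bool = True) -> "SVCallset":
        """Restrict to records passing the caller's quality filters."""
        if not pass_only:
            return self
        return SVCallset(
            sample=self.sample,
            method=self.method,
            records=[r for r in self.records if r.is_pass],
            translocations=[t for t in self.translocations if t.is_pass],
            unpaired_bnds=[r for r in self.unpaired_bnds if r.is_pass],
        )


@dataclass(frozen=True)
class ArmDefinition:
    """Chromosome p/q arm spans derived from cytogenetic bands."""

    arms: Mapping[tuple, GenomicInterval]

    def __post_init__(self) -> None:
        for chrom in {c for c, _ in self.arms}:
            p = self.arms.get((chrom, "p"))
            q = self.arms.get((chrom, "q"))
            if p is not None and q is not None:
                if p.end > q.start:
                    raise ValueError(f"p/q arms overlap on chromosome {chrom}")

    def get(self, chrom: str, arm: str) -> Optional[GenomicInterval]:
        return self.arms.get((chrom, arm))

    def __getitem__(self, key: tuple) -> GenomicInterval:
        return self.arms[key]

    def __contains__(self, key: tuple) -> bool:
        return key in self.arms

    def chromosomes(self) -> list:
        return sorted({c for c, _ in self.arms})

    def items(self):
        return self.arms.items()


@dataclass(frozen=True)
class TruthTable:
    """Binary sample x event truth labels (e.g., clinical FISH findings)."""

    table: pd.DataFrame  # index: samples, columns: event ids, values 0/1

    def __post_init__(self) -> None:
        if self.table.empty:
            raise SVFormatError("truth table is empty")
        bad = self.table.isna()
        if bad.any().any():
            sample = self.table.index[bad.any(axis=1)][0]
            event = self.table.columns[bad.any(axis=0)][0]
            raise SVFormatError(f"missing truth cell for sample {sample!r}, event {event!r}")
        values = set(self.table.values.ravel().tolist())
        if not values <= {0, 1}:
            raise SVFormatError(f"truth cells must be 0/1, found {sorted(values - {0, 1})}")

    @property
    def samples(self) -> list:
        return list(self.table.index)

    @property
    def events(self) -> list:
        return list(self.table.columns)

    @property
    def P(self) -> int:
        """Number of positive (sample, event) cells."""
        return int(self.table.values.sum())

    @property
    def N(self) -> int:
        """Number of negative (sample, event) cells."""
        return int(self.table.size - self.P)


# --------------------------------------------------------------------------
# VCF reading (Manta dialect)
# --------------------------------------------------------------------------

_BND_ALT_RE = re.compile(
    r"""^(?:
        (?P<t1>[A-Za-z.*]*)\[(?P<chrom1>[^:\[\]]+):(?P<pos1>\d+)\[   |
        (?P<t2>[A-Za-z.*]*)\](?P<chrom2>[^:\[\]]+):(?P<pos2>\d+)\]   |
        \](?P<chrom3>[^:\[\]]+):(?P<pos3>\d+)\](?P<t3>[A-Za-z.*]*)   |
        \[(?P<chrom4>[^:\[\]]+):(?P<pos4>\d+)\[(?P<t4>[A-Za-z.*]*)
    )$""",
    re.VERBOSE,
)

_BND_CLASS_BY_GROUP = {
    "chrom1": BndOrientation.T_RIGHT_FWD,
    "chrom2": BndOrientation.T_LEFT_REV,
    "chrom3": BndOrientation.LEFT_FWD,
    "chrom4": BndOrientation.RIGHT_REV,
}


def parse_bnd_alt(alt: str, chrom_policy: str = "strip") -> tuple:
    """Parse a BND ALT string into (orientation, mate chrom, mate 0-based pos)."""
    m = _BND_ALT_RE.match(alt)
    if m is None:
        raise SVFormatError(f"malformed BND ALT string: {alt!r}")
    for group, orientation in _BND_CLASS_BY_GROUP.items():
        chrom = m.group(group)
        if chrom is not None:
            pos = int(m.group("pos" + group[-1]))
            return orientation, normalize_chrom(chrom, chrom_policy), pos - 1
    raise SVFormatError(f"malformed BND ALT string: {alt!r}")  # pragma: no cover


def _scalar(value):
    """INFO values declared Number=. come back as tuples; unwrap singletons."""
    if isinstance(value, tuple):
        return value[0] if value else None
    return value


def read_sv_vcf(
    path: Union[str, Path],
    sample: str,
    method: str,
    chrom_policy: str = "strip",
) -> SVCallset:
    """Read a Manta-dialect SV VCF into a normalized callset.

    Every record must carry an SVTYPE INFO key. 1-based VCF coordinates
    become 0-based half-open intervals. FILTER values are retained, not
    applied: filtering is a downstream decision. BND records land in
    ``unpaired_bnds`` until :func:`pair_breakends` assembles them.

    Parameters
    ----------
    path : VCF file (plain or bgzipped).
    sample, method : labels attached to every record.
    chrom_policy : chromosome-name normalization ("strip"/"add"/"keep").
    """
    callset = SVCallset(sample=sample, method=method)
    vcf = VCF(str(path))
    try:
        n_header_lines = vcf.raw_header.count("\n")
        for idx, rec in enumerate(vcf):
            line_no = n_header_lines + idx + 1
            svtype = _scalar(rec.INFO.get("SVTYPE"))
            if svtype is None:
                raise SVFormatError(
                    f"record at line {line_no} ({rec.CHROM}:{rec.POS}) has no SVTYPE"
                )
            if svtype not in SV_TYPES:
                raise SVFormatError(
                    f"record at line {line_no} has unsupported SVTYPE {svtype!r}"
                )
            chrom = normalize_chrom(rec.CHROM, chrom_policy)
            svlen = _scalar(rec.INFO.get("SVLEN"))
            svlen = int(svlen) if svlen is not None else None
            filters = frozenset(rec.FILTERS)  # empty for '.', {'PASS'} for PASS
            qual = float(rec.QUAL) if rec.QUAL is not None else None
            record_id = rec.ID or f"rec{idx}"

            if svtype == "BND":
                alt = rec.ALT[0] if rec.ALT else ""
                try:
                    orientation, mate_chrom, mate_pos = parse_bnd_alt(alt, chrom_policy)
                except SVFormatError as exc:
                    raise SVFormatError(f"record {record_id}: {exc}") from exc
                mate_id = _scalar(rec.INFO.get("MATEID"))
                sv = SVRecord(
                    record_id=record_id,
                    sample=sample,
                    method=method,
                    svtype="BND",
                    svlen=svlen,
                    quality=qual,
                    filters=filters,
                    mate_id=mate_id,
                    breakend=Breakend(chrom, rec.POS - 1, orientation),
                    mate_breakend=Breakend(mate_chrom, mate_pos, orientation),
                )
                callset.unpaired_bnds.append(sv)
            else:
                start = rec.POS - 1  # VCF POS is 1-based
                end_info = rec.INFO.get("END")
                if end_info is not None:
                    # 1-based inclusive END == 0-based exclusive end
                    end = int(end_info)
                elif svlen is not None and svtype in ("DEL", "DUP", "INV"):
                    end = start + abs(svlen)
                else:
                    end = rec.end
                if end <= start:  # point insertions
                    end = start + 1
                sv = SVRecord(
                    record_id=record_id,
                    sample=sample,
                    method=method,
                    svtype=svtype,
                    interval=GenomicInterval(chrom, start, end),
                    svlen=svlen,
                    quality=qual,
                    filters=filters,
                )
            callset.records.append(sv)
    finally:
        vcf.close()
    return callset


def pair_breakends(callset: SVCallset) -> SVCallset:
    """Assemble mutually referencing BND records into translocation events.

    Two BND records form one event when each names the other via MATEID.
    BNDs whose mate is absent or non-reciprocal stay in
    ``unpaired_bnds`` — pairing failures are recorded, never raised or
    silently dropped. Idempotent and invariant to record order.
    """
    candidates = list(callset.unpaired_bnds)
    by_id = {}
    for rec in candidates:
        if rec.record_id in by_id:
            raise SVFormatError(f"duplicate BND record id {rec.record_id!r}")
        by_id[rec.record_id] = rec

    events = list(callset.translocations)
    unpaired = []
    consumed = set()
    for rec in sorted(candidates, key=lambda r: (r.breakend.chrom, r.breakend.pos, r.record_id)):
        if rec.record_id in consumed:
            continue
        mate = by_id.get(rec.mate_id) if rec.mate_id else None
        if mate is not None and mate.record_id not in consumed and mate.mate_id == rec.record_id:
            events.append(
                TranslocationEvent(
                    breakend_a=rec.breakend,
                    breakend_b=mate.breakend,
                    source_ids=(rec.record_id, mate.record_id),
                    filters=rec.filters | mate.filters,
                    quality=_min_quality(rec.quality, mate.quality),
                )
            )
            consumed.add(rec.record_id)
            consumed.add(mate.record_id)
        else:
            unpaired.append(rec)

    # a record whose mate was consumed by someone else stays unpaired
    unpaired = [r for r in unpaired if r.record_id not in consumed]
    return SVCallset(
        sample=callset.sample,
        method=callset.method,
        records=list(callset.records),
        translocations=events,
        unpaired_bnds=unpaired,
    )


def _min_quality(a: Optional[float], b: Optional[float]) -> Optional[float]:
    vals = [v for v in (a, b) if v is not None]
    return min(vals) if vals else None


# --------------------------------------------------------------------------
# Companion tables
# --------------------------------------------------------------------------


def read_truth_table(path: Union[str, Path]) -> TruthTable:
    """Read a delimited sample x event 0/1 truth table (first column: sample)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise SVFormatError(f"truth table {path} is empty")
    validated = TruthTable(df)  # raises on missing or non-binary cells
    return TruthTable(validated.table.astype(int))


def read_arm_map(path: Union[str, Path], chrom_policy: str = "strip") -> ArmDefinition:
    """Build p/q arm intervals from a UCSC cytoBand file.

    Each arm's interval is the union span (min start, max end) of that
    chromosome's p* or q* bands. A chromosome with bands but no q bands
    is rejected: every real chromosome has a q arm.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "band", "stain"],
        dtype={"chrom": str, "band": str},
    )
    if df.empty:
        raise SVFormatError(f"cytoBand file {path} is empty")
    arms = {}
    df["chrom"] = df["chrom"].map(lambda c: normalize_chrom(c, chrom_policy))
    for chrom, sub in df.groupby("chrom", sort=False):
        for arm in ("p", "q"):
            bands = sub[sub["band"].str.startswith(arm)]
            if not bands.empty:
                arms[(chrom, arm)] = GenomicInterval(
                    chrom, int(bands["start"].min()), int(bands["end"].max())
                )
        if (chrom, "q") not in arms:
            raise SVFormatError(f"chromosome {chrom} has no q bands")
    return ArmDefinition(arms)


def read_hotspot_catalog(path: Union[str, Path], chrom_policy: str = "strip"):
    """Read a hotspot catalog TSV (chrom, start, end, hotspot_id, category)."""
    from svconcord.hotspots import HotspotCatalog, HotspotEntry, HOTSPOT_CATEGORIES

    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "hotspot_id", "category"],
        dtype={"chrom": str, "hotspot_id": str, "category": str},
        comment="#",
        skip_blank_lines=True,
    )
    entries = []
    seen = set()
    for row in df.itertuples(index=False):
        if row.category not in HOTSPOT_CATEGORIES:
            raise SVFormatError(
                f"unknown hotspot category {row.category!r} for {row.hotspot_id}"
            )
        if row.hotspot_id in seen:
            raise SVFormatError(f"duplicate hotspot id {row.hotspot_id!r}")
        seen.add(row.hotspot_id)
        entries.append(
            HotspotEntry(
                hotspot_id=row.hotspot_id,
                region=GenomicInterval(
                    normalize_chrom(row.chrom, chrom_policy), int(row.start), int(row.end)
                ),
                category=row.category,
            )
        )
    return HotspotCatalog(entries=tuple(entries))


# --------------------------------------------------------------------------
# BEDPE writing
# --------------------------------------------------------------------------

_BEDPE_HEADER = (
    "#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tname\tscore\tsvtype\tsvlen\tfilters\n"
)


def write_bedpe(callset: SVCallset, path: Union[str, Path]) -> None:
    """Write a callset as BEDPE (0-based half-open breakpoint pairs).

    Interval records emit their two breakpoints as single-base features
    (start1 = interval start, end2 = interval end), so the original
    coordinates are recoverable bit-exactly. Translocations and unpaired
    BNDs emit one row per adjacency.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_BEDPE_HEADER)
        for rec in callset.records:
            if rec.svtype == "BND":
                continue
            iv = rec.interval
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.start + 1),
                        iv.chrom,
                        str(iv.end - 1),
                        str(iv.end),
                        rec.record_id,
                        _fmt(rec.quality),
                        rec.svtype,
                        _fmt(rec.svlen),
                        ";".join(sorted(rec.filters)) or ".",
                    ]
                )
                + "\n"
            )
        for ev in callset.translocations:
            fh.write(
                "\t".join(
                    [
                        ev.breakend_a.chrom,
                        str(ev.breakend_a.pos),
                        str(ev.breakend_a.pos + 1),
                        ev.breakend_b.chrom,
                        str(ev.breakend_b.pos),
                        str(ev.breakend_b.pos + 1),
                        "|".join(ev.source_ids),
                        _fmt(ev.quality),
                        "BND",
                        ".",
                        ";".join(sorted(ev.filters)) or ".",
                    ]
                )
                + "\n"
            )
        for rec in callset.unpaired_bnds:
            mate = rec.mate_breakend
            fh.write(
                "\t".join(
                    [
                        rec.breakend.chrom,
                        str(rec.breakend.pos),
                        str(rec.breakend.pos + 1),
                        mate.chrom if mate else ".",
                        str(mate.pos) if mate else ".",
                        str(mate.pos + 1) if mate else ".",
                        rec.record_id,
                        _fmt(rec.quality),
                        "BND",
                        ".",
                        ";".join(sorted(rec.filters)) or ".",
                    ]
                )
                + "\n"
            )


def _fmt(value) -> str:
    if value is None:
        return "."
    if isinstance(value, float) and value.is_integer():
        return str(int(value))
    return str(value)


def read_bedpe(path: Union[str, Path]) -> pd.DataFrame:
    """Read a BEDPE written by :func:`write_bedpe` into a DataFrame."""
    return pd.read_csv(path, sep="\t", header=0, dtype={"#chrom1": str, "chrom2": str})
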