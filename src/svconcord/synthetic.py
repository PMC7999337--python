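"""Synthetic Manta-dialect callsets with platform-specific signatures.

The generator emulates the statistical structure of the two exome
platforms' candidate SV output: the WES-like profile is dominated by
deletions and insertions (DEL 56.3%, INS 32.6%, BND 6.7%, DUP 3.3%,
INV 1.2%), while the linked-read-like profile is dominated by inversions
(92.4%) and detects no insertions. Clinical panel events are planted per
sample and emitted with a configurable per-method detection sensitivity,
enabling end-to-end parameter-recovery experiments against the ROC
stage.

The genome model is the chromosome-arm map itself: calls are placed
uniformly within arms, weighted by arm length. Coordinates, not
sequence, drive every downstream computation, so no reference FASTA is
needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from svconcord.cytogenetics import CytoEventSpec, PredictionMatrix, build_event_panel
from svconcord.io import (
    ArmDefinition,
    Breakend,
    BndOrientation,
    GenomicInterval,
    SVCallset,
    SVRecord,
    TranslocationEvent,
    TruthTable,
)
from svconcord.short_variants import RULE_NAMES, ShortVariant

#: Published WES-like SV type shares (percentages summing to 100.1 before
#: renormalization).
WES_COMPOSITION = {"DEL": 0.563, "INS": 0.326, "BND": 0.067, "DUP": 0.033, "INV": 0.012}

#: Linked-read-like shares: inversion-dominated, zero insertions; the
#: non-INV residual is split DUP-heavy, echoing the platforms' relative
#: counts. Declared convention, overridable.
LINKEDREAD_COMPOSITION = {
    "INV": 0.924,
    "DUP": 0.066,
    "DEL": 0.003,
    "BND": 0.003,
    "INS": 0.0,
}

#: Default log-normal size parameters (median bp, sigma of log size).
DEFAULT_SIZES = {
    "DEL": (5_000, 1.0),
    "DUP": (5_000, 1.0),
    "INV": (5_000, 1.0),
    "INS": (100, 0.8),
}


@dataclass(frozen=True)
class SyntheticProfile:
    """Statistical signature of one platform's candidate callset.

    composition : expected share of calls per SV type (a translocation
        adjacency counts as one call). Renormalized with a warning when
        the shares do not sum to 1, as happens with published rounded
        percentages.
    size_distribution : per-type log-normal parameters (median bp, sigma).
    n_calls : expected total background calls per sample.
    fp_rate : fraction of ``n_calls`` emitted as background noise not
        derived from planted truth events.
    pass_rate : fraction of background calls that carry FILTER=PASS; the
        rest are retained as quality-failed candidates, emulating how
        heavily the caller's filters thin a candidate callset.
    sub50_fraction : fraction of calls drawn below the 50 bp SV floor.
    """

    name: str
    composition: Mapping[str, float]
    size_distribution: Mapping[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_SIZES)
    )
    n_calls: int = 1000
    fp_rate: float = 1.0
    pass_rate: float = 1.0
    sub50_fraction: float = 0.05

    def __post_init__(self) -> None:
        comp = dict(self.composition)
        if any(v < 0 for v in comp.values()):
            raise ValueError("composition proportions must be non-negative")
        total = sum(comp.values())
        if total <= 0:
            raise ValueError("composition must have positive mass")
        if abs(total - 1.0) > 1e-9:
            warnings.warn(
                f"profile {self.name!r}: composition sums to {total:.4g}; renormalizing",
                stacklevel=2,
            )
            comp = {k: v / total for k, v in comp.items()}
        object.__setattr__(self, "composition", comp)
        if not 0 <= self.fp_rate <= 1:
            raise ValueError("fp_rate must lie in [0, 1]")
        if not 0 <= self.pass_rate <= 1:
            raise ValueError("pass_rate must lie in [0, 1]")
        if not 0 <= self.sub50_fraction <= 1:
            raise ValueError("sub50_fraction must lie in [0, 1]")


def default_profiles() -> dict:
    """The two platform signatures as immutable named profiles."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # published shares sum to 100.1%
        return {
            "wes_like": SyntheticProfile(
                name="wes_like",
                composition=WES_COMPOSITION,
                n_calls=4065,
                pass_rate=0.024,  # ~99 of 4065 candidates survive filtering
            ),
            "linkedread_like": SyntheticProfile(
                name="linkedread_like",
                composition=LINKEDREAD_COMPOSITION,
                n_calls=18455,
                pass_rate=0.016,  # ~304 of 18455 candidates survive filtering
            ),
        }


@dataclass(frozen=True)
class GroundTruth:
    """Planted panel events per sample, plus per-kind detection sensitivity."""

    planted: Mapping[str, frozenset]  # sample -> set of planted event ids
    sensitivity: Mapping[str, float] = field(default_factory=dict)  # kind -> s

    def __post_init__(self) -> None:
        for kind, s in self.sensitivity.items():
            if not 0 <= s <= 1:
                raise ValueError(f"sensitivity for {kind!r} must be in [0,1], got {s}")


def simulate_truth(
    n_samples: int,
    panel: Sequence[CytoEventSpec],
    prevalence: Union[float, Mapping[str, float]] = 0.175,
    seed: Optional[int] = None,
) -> tuple:
    """Plant panel events per sample by independent Bernoulli draws.

    ``prevalence`` is a per-event positive probability (scalar or map by
    event id). Returns (TruthTable, GroundTruth). The default prevalence
    of 0.175 yields an expected 14 positives over an 8-sample x 10-event
    grid, matching the positive density of a small clinical cohort.
    """
    if n_samples < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    event_ids = [spec.event_id for spec in panel]
    if isinstance(prevalence, Mapping):
        probs = {e: float(prevalence[e]) for e in event_ids}
    else:
        probs = {e: float(prevalence) for e in event_ids}
    for e, p in probs.items():
        if not 0 <= p <= 1:
            raise ValueError(f"prevalence for {e!r} must be in [0,1], got {p}")

    samples = [f"S{i + 1:02d}" for i in range(n_samples)]
    cells = {
        s: {e: int(rng.random() < probs[e]) for e in event_ids} for s in samples
    }
    table = pd.DataFrame.from_dict(cells, orient="index")[event_ids].astype(int)
    planted = {
        s: frozenset(e for e in event_ids if cells[s][e] == 1) for s in samples
    }
    return TruthTable(table), GroundTruth(planted=planted)


def _resolve_sensitivity(sensitivity, kind: str) -> float:
    if isinstance(sensitivity, Mapping):
        return float(sensitivity.get(kind, sensitivity.get("default", 1.0)))
    return float(sensitivity)


def _draw_size(rng, profile: SyntheticProfile, svtype: str) -> int:
    if rng.random() < profile.sub50_fraction:
        return int(rng.integers(1, 50))
    median, sigma = profile.size_distribution.get(svtype, (5_000, 1.0))
    size = int(round(median * float(np.exp(sigma * rng.standard_normal()))))
    return max(size, 50)


def _arm_weights(arms: ArmDefinition) -> tuple:
    keys = sorted(arms.arms)
    lengths = np.array([len(arms[k]) for k in keys], dtype=float)
    return keys, lengths / lengths.sum()


def _place_interval(rng, arms, keys, weights, size: int) -> GenomicInterval:
    key = keys[rng.choice(len(keys), p=weights)]
    region = arms[key]
    size = min(size, len(region))
    start = int(rng.integers(region.start, region.end - size + 1))
    return GenomicInterval(region.chrom, start, start + size)


def _interval_record(rec_id, sample, method, svtype, iv, qual, rng,
                     filters=frozenset({"PASS"})) -> SVRecord:
    svlen = len(iv) if svtype != "DEL" else -len(iv)
    return SVRecord(
        record_id=rec_id,
        sample=sample,
        method=method,
        svtype=svtype,
        interval=iv,
        svlen=svlen,
        quality=qual,
        filters=filters,
    )


def _bnd_pair(rec_id_base, sample, method, be_a: Breakend, be_b: Breakend, qual,
              filters=frozenset({"PASS"})) -> tuple:
    id_a, id_b = f"{rec_id_base}:0", f"{rec_id_base}:1"
    rec_a = SVRecord(
        record_id=id_a, sample=sample, method=method, svtype="BND",
        quality=qual, filters=filters, mate_id=id_b,
        breakend=be_a, mate_breakend=replace(be_b, orientation=be_a.orientation),
    )
    rec_b = SVRecord(
        record_id=id_b, sample=sample, method=method, svtype="BND",
        quality=qual, filters=filters, mate_id=id_a,
        breakend=be_b, mate_breakend=replace(be_a, orientation=be_b.orientation),
    )
    return rec_a, rec_b


def generate_callset(
    profile: SyntheticProfile,
    truth_row: Mapping[str, int],
    sensitivity: Union[float, Mapping[str, float]],
    arms: ArmDefinition,
    seed: Optional[int] = None,
    sample: str = "S01",
    method: Optional[str] = None,
    panel: Optional[Sequence[CytoEventSpec]] = None,
    n_calls: Optional[int] = None,
    vcf_path: Optional[Union[str, Path]] = None,
) -> SVCallset:
    """Generate one sample's callset: planted event support plus background.

    Each planted event (truth cell = 1) emits one supporting PASS call
    with probability ``sensitivity`` (scalar, or map keyed by event
    kind). Background calls — ``round(n_calls * fp_rate)`` of them — are
    drawn from the profile's type composition and size distributions at
    arm-weighted random placements. Breakend adjacencies are emitted as
    mutually MATEID-paired BND record pairs, so the callset round-trips
    through the VCF reader and breakend pairing without loss. The
    returned callset already has its translocations assembled.
    """
    rng = np.random.default_rng(seed)
    method = method or profile.name
    panel = list(panel) if panel is not None else build_event_panel(arms)
    keys, weights = _arm_weights(arms)
    spec_by_id = {spec.event_id: spec for spec in panel}

    records: list = []
    translocations: list = []
    counter = 0

    def next_id(prefix: str) -> str:
        nonlocal counter
        counter += 1
        return f"Synth{prefix}:{sample}:{counter}"

    def qual() -> float:
        return float(rng.integers(100, 1000))

    # planted event support
    for event_id in sorted(e for e, v in truth_row.items() if v):
        spec = spec_by_id.get(event_id)
        if spec is None:
            raise ValueError(f"truth row names unknown panel event {event_id!r}")
        s = _resolve_sensitivity(sensitivity, spec.kind)
        if rng.random() >= s:
            continue
        q = qual()
        if spec.kind == "translocation":
            chrom_a, chrom_b = spec.chrom_pair
            be_a = Breakend(chrom_a, _rand_pos(rng, arms, chrom_a), BndOrientation.T_RIGHT_FWD)
            be_b = Breakend(chrom_b, _rand_pos(rng, arms, chrom_b), BndOrientation.LEFT_FWD)
            rec_a, rec_b = _bnd_pair(next_id("BND"), sample, method, be_a, be_b, q)
            records.extend([rec_a, rec_b])
            translocations.append(
                TranslocationEvent(
                    breakend_a=be_a, breakend_b=be_b,
                    source_ids=(rec_a.record_id, rec_b.record_id),
                    filters=frozenset({"PASS"}), quality=q,
                )
            )
        else:
            svtype = "DEL" if spec.kind == "arm_loss" else "DUP"
            region = spec.region
            size = min(_draw_size(rng, profile, svtype), len(region))
            size = max(size, 50)  # planted support is a bona fide SV
            start = int(rng.integers(region.start, region.end - size + 1))
            iv = GenomicInterval(region.chrom, start, start + size)
            records.append(
                _interval_record(next_id(svtype), sample, method, svtype, iv, q, rng)
            )

    # background calls from the profile composition
    n_total = profile.n_calls if n_calls is None else n_calls
    n_background = int(round(n_total * profile.fp_rate))
    types = sorted(profile.composition)
    probs = np.array([profile.composition[t] for t in types])
    draws = rng.choice(len(types), size=n_background, p=probs)
    for t_idx in draws:
        svtype = types[t_idx]
        q = qual()
        filt = frozenset(
            {"PASS"} if rng.random() < profile.pass_rate else {"MinQual"}
        )
        if svtype == "BND":
            chrom_a, chrom_b = _rand_chrom_pair(rng, arms)
            be_a = Breakend(chrom_a, _rand_pos(rng, arms, chrom_a), BndOrientation.T_RIGHT_FWD)
            be_b = Breakend(chrom_b, _rand_pos(rng, arms, chrom_b), BndOrientation.LEFT_FWD)
            rec_a, rec_b = _bnd_pair(next_id("BND"), sample, method, be_a, be_b, q,
                                     filters=filt)
            records.extend([rec_a, rec_b])
            translocations.append(
                TranslocationEvent(
                    breakend_a=be_a, breakend_b=be_b,
                    source_ids=(rec_a.record_id, rec_b.record_id),
                    filters=filt, quality=q,
                )
            )
        elif svtype == "INS":
            key = keys[rng.choice(len(keys), p=weights)]
            region = arms[key]
            pos = int(rng.integers(region.start, region.end))
            size = _draw_size(rng, profile, "INS")
            records.append(
                SVRecord(
                    record_id=next_id("INS"), sample=sample, method=method,
                    svtype="INS",
                    interval=GenomicInterval(region.chrom, pos, pos + 1),
                    svlen=size, quality=q, filters=filt,
                )
            )
        else:
            iv = _place_interval(rng, arms, keys, weights, _draw_size(rng, profile, svtype))
            records.append(
                _interval_record(next_id(svtype), sample, method, svtype, iv, q, rng,
                                 filters=filt)
            )

    callset = SVCallset(
        sample=sample, method=method, records=records,
        translocations=translocations, unpaired_bnds=[],
    )
    if vcf_path is not None:
        write_manta_vcf(callset, vcf_path, arms)
    return callset


def _rand_pos(rng, arms: ArmDefinition, chrom: str) -> int:
    spans = [iv for (c, _), iv in arms.items() if c == chrom]
    if not spans:
        raise ValueError(f"arm map lacks chromosome {chrom!r}")
    lengths = np.array([len(iv) for iv in spans], dtype=float)
    iv = spans[rng.choice(len(spans), p=lengths / lengths.sum())]
    return int(rng.integers(iv.start, iv.end))


def _rand_chrom_pair(rng, arms: ArmDefinition) -> tuple:
    chroms = arms.chromosomes()
    if len(chroms) < 2:
        raise ValueError("need at least two chromosomes for translocations")
    i, j = rng.choice(len(chroms), size=2, replace=False)
    return chroms[int(i)], chroms[int(j)]


# --------------------------------------------------------------------------
# Manta-dialect VCF writer
# --------------------------------------------------------------------------

_VCF_INFO_HEADER = """\
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">
##INFO=<ID=SVLEN,Number=.,Type=Integer,Description="Difference in length between REF and ALT alleles">
##INFO=<ID=MATEID,Number=.,Type=String,Description="ID of mate breakend">
##INFO=<ID=CIPOS,Number=2,Type=Integer,Description="Confidence interval around POS">
##ALT=<ID=DEL,Description="Deletion">
##ALT=<ID=DUP,Description="Duplication">
##ALT=<ID=INS,Description="Insertion">
##ALT=<ID=INV,Description="Inversion">
##FILTER=<ID=MinQual,Description="Quality below threshold">
"""


def write_manta_vcf(
    callset: SVCallset, path: Union[str, Path], arms: ArmDefinition
) -> None:
    """Write a callset as a Manta-dialect VCF (deterministic text).

    Contig lengths come from the arm map (end of the q arm). BND
    adjacencies are written as mutually MATEID-referencing record pairs
    with bracket-notation ALTs; the file round-trips through
    ``read_sv_vcf`` + ``pair_breakends``.
    """
    lines = ["##fileformat=VCFv4.1", "##source=svconcord-synthetic"]
    for chrom in callset_contigs(callset, arms):
        length = max(
            iv.end for (c, _), iv in arms.items() if c == chrom
        ) if any(c == chrom for c, _ in arms.arms) else 300_000_000
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.extend(_VCF_INFO_HEADER.rstrip("\n").split("\n"))
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")

    rows = []
    for rec in callset.records:
        qual = _fmt_qual(rec.quality)
        filt = ";".join(sorted(rec.filters)) or "."
        if rec.svtype == "BND":
            be, mate = rec.breakend, rec.mate_breakend
            alt = _bnd_alt("N", mate.chrom, mate.pos + 1, be.orientation)
            info = f"SVTYPE=BND;MATEID={rec.mate_id}" if rec.mate_id else "SVTYPE=BND"
            rows.append(
                (be.chrom, be.pos + 1,
                 f"{be.chrom}\t{be.pos + 1}\t{rec.record_id}\tN\t{alt}\t{qual}\t{filt}\t{info}")
            )
        else:
            iv = rec.interval
            pos = iv.start + 1
            info_parts = [f"SVTYPE={rec.svtype}", f"END={iv.end}"]
            if rec.svlen is not None:
                info_parts.append(f"SVLEN={rec.svlen}")
            rows.append(
                (iv.chrom, pos,
                 f"{iv.chrom}\t{pos}\t{rec.record_id}\tN\t<{rec.svtype}>\t{qual}\t{filt}\t"
                 + ";".join(info_parts))
            )
    rows.sort(key=lambda r: (r[0], r[1]))
    lines.extend(r[2] for r in rows)
    Path(path).write_text("\n".join(lines) + "\n")


def callset_contigs(callset: SVCallset, arms: ArmDefinition) -> list:
    chroms = set(arms.chromosomes())
    for rec in callset.records:
        if rec.interval is not None:
            chroms.add(rec.interval.chrom)
        if rec.breakend is not None:
            chroms.add(rec.breakend.chrom)
    return sorted(chroms)


def _fmt_qual(q) -> str:
    if q is None:
        return "."
    return str(int(q)) if float(q).is_integer() else f"{q:g}"


def _bnd_alt(base: str, mate_chrom: str, mate_pos_1based: int, orientation) -> str:
    p = f"{mate_chrom}:{mate_pos_1based}"
    if orientation == BndOrientation.T_RIGHT_FWD:
        return f"{base}[{p}["
    if orientation == BndOrientation.T_LEFT_REV:
        return f"{base}]{p}]"
    if orientation == BndOrientation.LEFT_FWD:
        return f"]{p}]{base}"
    return f"[{p}[{base}"


# --------------------------------------------------------------------------
# Synthetic short-variant tables
# --------------------------------------------------------------------------

_RULE_BREAKERS = {
    "caller_filters": dict(filters=frozenset({"t_lod_fstar"})),
    "region": dict(region_class="intronic"),
    "function": dict(exonic_function="synonymous"),
    "pop_af": dict(pop_af=(0.05, 0.0, 0.0)),
    "qual": dict(qual=10.0),
    "depth": dict(depth=5),
    "vaf": dict(vaf=0.005),
    "sor": dict(sor=5.0),  # SNV bound is 3; indel variants get 15 instead
}

_BASES = ("A", "C", "G", "T")


def generate_short_variants(
    n: int,
    per_rule_fail_fractions: Optional[Mapping[str, float]] = None,
    seed: Optional[int] = None,
    sample: str = "S01",
    dataset: str = "WES",
) -> list:
    """Generate annotated short variants engineered against the cascade.

    Each variant either passes every filter rule or fails exactly one
    designated rule; rule assignment is multinomial with the given fail
    fractions (summing to at most 1). The expected kept fraction is
    1 - sum(fractions).
    """
    fractions = dict(per_rule_fail_fractions or {})
    unknown = set(fractions) - set(RULE_NAMES)
    if unknown:
        raise ValueError(f"unknown rules in fail fractions: {sorted(unknown)}")
    total_fail = sum(fractions.values())
    if total_fail > 1 + 1e-12:
        raise ValueError(f"fail fractions sum to {total_fail:.3g} > 1")

    rng = np.random.default_rng(seed)
    outcomes = list(fractions) + ["__pass__"]
    probs = np.array([fractions[r] for r in fractions] + [max(0.0, 1 - total_fail)])
    probs = probs / probs.sum()
    assignment = rng.choice(len(outcomes), size=n, p=probs)

    variants = []
    for i in range(n):
        is_indel = rng.random() < 0.2
        ref = _BASES[rng.integers(0, 4)]
        if is_indel:
            alt = ref + "".join(_BASES[rng.integers(0, 4)] for _ in range(int(rng.integers(1, 6))))
        else:
            alt = _BASES[(rng.integers(1, 4) + _BASES.index(ref)) % 4]
        base = dict(
            chrom=str(int(rng.integers(1, 23))),
            pos=int(rng.integers(0, 100_000_000)),
            ref=ref,
            alt=alt,
            region_class="exonic",
            exonic_function="nonsynonymous",
            pop_af=(0.0, None, 0.001),
            qual=float(rng.uniform(40, 100)),
            depth=int(rng.integers(10, 200)),
            vaf=float(rng.uniform(0.02, 0.30)),
            sor=float(rng.uniform(0, 3.0 if not is_indel else 11.0)),
            gene="",
            sample=sample,
            dataset=dataset,
            filters=frozenset({"PASS"}),
        )
        rule = outcomes[assignment[i]]
        if rule != "__pass__":
            override = dict(_RULE_BREAKERS[rule])
            if rule == "sor" and is_indel:
                override = dict(sor=15.0)
            if rule == "vaf" and rng.random() < 0.5:
                override = dict(vaf=0.5)
            base.update(override)
        variants.append(ShortVariant(**base))
    return variants


def write_variant_table(variants: Iterable[ShortVariant], path: Union[str, Path]) -> None:
    """Write variants as the TSV dialect read by ``read_variant_table``."""
    rows = []
    for v in variants:
        af = [("" if x is None else x) for x in v.pop_af]
        rows.append(
            {
                "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                "region_class": v.region_class, "exonic_function": v.exonic_function,
                "af1": af[0], "af2": af[1], "af3": af[2],
                "qual": v.qual, "depth": v.depth, "vaf": v.vaf, "sor": v.sor,
                "gene": v.gene, "filters": ";".join(sorted(v.filters)),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Parameter recovery helpers
# --------------------------------------------------------------------------


def write_cytoband(arms: ArmDefinition, path: Union[str, Path]) -> None:
    """Write an arm map as a minimal UCSC cytoBand file (one band per arm)."""
    lines = []
    for (chrom, arm), iv in sorted(arms.items()):
        lines.append(f"{chrom}\t{iv.start}\t{iv.end}\t{arm}11\tgneg")
    Path(path).write_text("\n".join(lines) + "\n")


def synthetic_hotspot_catalog(
    arms: ArmDefinition,
    n_gain: int = 49,
    n_loss: int = 19,
    n_fragile: int = 0,
    width: int = 2_000_000,
    seed: Optional[int] = None,
):
    """A synthetic stand-in for a published hotspot catalog.

    Regions are placed at arm-weighted random positions; the default
    category counts mirror the published catalog's 49 gain / 19 loss
    split. This is simulated data, not the published table.
    """
    from svconcord.hotspots import HotspotCatalog, HotspotEntry

    rng = np.random.default_rng(seed)
    keys, weights = _arm_weights(arms)
    entries = []
    spec = [("gain", n_gain), ("loss", n_loss), ("fragile", n_fragile)]
    idx = 0
    for category, count in spec:
        for _ in range(count):
            idx += 1
            iv = _place_interval(rng, arms, keys, weights, width)
            entries.append(
                HotspotEntry(hotspot_id=f"HS{idx:03d}", region=iv, category=category)
            )
    return HotspotCatalog(entries=tuple(entries))


def write_hotspot_catalog(catalog, path: Union[str, Path]) -> None:
    """Write a catalog as the TSV dialect read by ``read_hotspot_catalog``."""
    lines = [
        f"{e.region.chrom}\t{e.region.start}\t{e.region.end}\t{e.hotspot_id}\t{e.category}"
        for e in catalog
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def estimate_sensitivity(pred: PredictionMatrix, truth: TruthTable) -> dict:
    """Fraction of truth-positive cells detected (score >= 1), with counts.

    Returns {"detected", "planted", "estimate"} — the raw ingredients for
    a binomial confidence interval on the detection sensitivity.
    """
    aligned = pred.table.loc[truth.samples, truth.events]
    positive = truth.table.values == 1
    detected = int(((aligned.values >= 1) & positive).sum())
    planted = int(positive.sum())
    return {
        "detected": detected,
        "planted": planted,
        "estimate": detected / planted if planted else float("nan"),
    }


def synthetic_arm_map(n_chromosomes: int = 22, seed: int = 0) -> ArmDefinition:
    """A compact synthetic arm map for simulation and tests.

    Chromosome sizes taper from 240 Mb down to 45 Mb, mimicking the
    human karyotype's scale; the centromere sits at 40% of each
    chromosome. Deterministic for a given seed.
    """
    arms = {}
    for i in range(1, n_chromosomes + 1):
        length = int(240e6 - (i - 1) * (195e6 / max(1, n_chromosomes - 1)))
        centromere = int(length * 0.4)
        chrom = str(i)
        arms[(chrom, "p")] = GenomicInterval(chrom, 0, centromere)
        arms[(chrom, "q")] = GenomicInterval(chrom, centromere, length)
    return ArmDefinition(arms)
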