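"""Somatic short-variant filter cascade, three-way overlap, driver matrix.

The post-calling cascade removes annotated somatic variants that fail
any of eight rules: caller filters, region class (intronic/intergenic),
exonic function (synonymous/non-frameshift), population allele frequency
above 1% in any of three reference populations, calling quality below
40, site depth below 10 reads, variant allele fraction outside
[2%, 30%], and strand-odds-ratio above 3 (SNVs) or 11 (indels). The
kept set is the conjunction of all rules and therefore independent of
rule order; the per-rule removal trace attributes each removed variant
to the first failing rule in the declared order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Tuple

import pandas as pd

VARIANT_CLASSES = ("SNV", "insertion", "deletion")
DATASET_LABELS = ("linked-read", "WES", "RNA-seq")

#: The five recurrently mutated myeloma driver genes checked by default.
DEFAULT_DRIVER_GENES = ("BRAF", "KRAS", "NRAS", "TP53", "FAM46C")


def classify_alleles(ref: str, alt: str) -> str:
    """SNV / insertion / deletion from REF/ALT lengths."""
    if len(ref) == len(alt) == 1:
        return "SNV"
    if len(alt) > len(ref):
        return "insertion"
    if len(alt) < len(ref):
        return "deletion"
    return "SNV"  # MNV treated as substitution


@dataclass(frozen=True)
class ShortVariant:
    """An annotated somatic short variant (0-based position)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    region_class: str = "exonic"
    exonic_function: str = "nonsynonymous"
    pop_af: tuple = (None, None, None)  # three population AFs; None = absent
    qual: float = 0.0
    depth: int = 0
    vaf: float = 0.0
    sor: float = 0.0
    gene: str = ""
    sample: str = ""
    dataset: str = "WES"
    filters: frozenset = frozenset({"PASS"})

    def __post_init__(self) -> None:
        if not 0 <= self.vaf <= 1:
            raise ValueError(f"vaf must be in [0,1], got {self.vaf}")
        for af in self.pop_af:
            if af is not None and not 0 <= af <= 1:
                raise ValueError(f"population AF must be in [0,1], got {af}")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")

    @property
    def variant_class(self) -> str:
        return classify_alleles(self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return self.variant_class != "SNV"

    def normalized_key(self) -> tuple:
        """(chrom, pos, ref, alt) after minimal-representation normalization."""
        pos, ref, alt = left_normalize(self.pos, self.ref, self.alt)
        return (self.chrom, pos, ref, alt)


def left_normalize(pos: int, ref: str, alt: str) -> tuple:
    """Reduce an allele pair to its minimal left-aligned representation.

    Shared suffix bases are trimmed first, then shared prefix bases
    (advancing the position), keeping at least one base on each allele.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the somatic filter cascade (defaults per protocol)."""

    require_pass: bool = True
    drop_region: tuple = ("intronic", "intergenic")
    drop_function: tuple = ("synonymous", "nonframeshift")
    max_pop_af: float = 0.01
    min_qual: float = 40.0
    min_depth: int = 10
    vaf_window: tuple = (0.02, 0.30)
    max_sor_snv: float = 3.0
    max_sor_indel: float = 11.0

    def __post_init__(self) -> None:
        if self.vaf_window[0] > self.vaf_window[1]:
            raise ValueError("vaf_window must be ordered (low, high)")
        for name in ("max_pop_af", "min_qual", "max_sor_snv", "max_sor_indel"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class FilterTrace:
    """Removal accounting: kept + sum of per-rule removals = input size."""

    n_input: int
    kept: int
    removed_by_rule: dict = field(default_factory=dict)

    def check_conservation(self) -> bool:
        return self.kept + sum(self.removed_by_rule.values()) == self.n_input


# Rule predicates return True when the variant PASSES the rule.
def _rule_pass(v: ShortVariant, cfg: FilterConfig) -> bool:
    return v.filters <= {"PASS", "."}


def _rule_region(v: ShortVariant, cfg: FilterConfig) -> bool:
    return v.region_class not in cfg.drop_region


def _rule_function(v: ShortVariant, cfg: FilterConfig) -> bool:
    return v.exonic_function not in cfg.drop_function


def _rule_pop_af(v: ShortVariant, cfg: FilterConfig) -> bool:
    # absent AF means the variant is novel: it passes
    return all(af is None or af <= cfg.max_pop_af for af in v.pop_af)


def _rule_qual(v: ShortVariant, cfg: FilterConfig) -> bool:
    return v.qual >= cfg.min_qual


def _rule_depth(v: ShortVariant, cfg: FilterConfig) -> bool:
    return v.depth >= cfg.min_depth


def _rule_vaf(v: ShortVariant, cfg: FilterConfig) -> bool:
    low, high = cfg.vaf_window
    return low <= v.vaf <= high


def _rule_sor(v: ShortVariant, cfg: FilterConfig) -> bool:
    bound = cfg.max_sor_indel if v.is_indel else cfg.max_sor_snv
    return v.sor <= bound


#: Cascade rules in declared order; attribution is first-fail.
FILTER_RULES = (
    ("caller_filters", _rule_pass),
    ("region", _rule_region),
    ("function", _rule_function),
    ("pop_af", _rule_pop_af),
    ("qual", _rule_qual),
    ("depth", _rule_depth),
    ("vaf", _rule_vaf),
    ("sor", _rule_sor),
)

RULE_NAMES = tuple(name for name, _ in FILTER_RULES)


def apply_filter_cascade(
    variants: Iterable[ShortVariant],
    cfg: Optional[FilterConfig] = None,
    rule_order: Optional[Sequence[str]] = None,
) -> Tuple[List[ShortVariant], FilterTrace]:
    """Apply the somatic filter cascade; return kept variants and a trace.

    A variant is kept iff it passes every rule; a removed variant is
    attributed to the first rule it fails, in ``rule_order`` (default:
    the declared cascade order). The kept set is order-invariant; only
    the attribution depends on the order.
    """
    cfg = cfg or FilterConfig()
    rules = dict(FILTER_RULES)
    order = list(rule_order) if rule_order is not None else list(RULE_NAMES)
    unknown = set(order) - set(rules)
    if unknown:
        raise ValueError(f"unknown filter rules: {sorted(unknown)}")

    active = [name for name in order if name != "caller_filters" or cfg.require_pass]
    kept = []
    removed = {name: 0 for name in active}
    n_input = 0
    for i, v in enumerate(variants):
        n_input += 1
        if not isinstance(v, ShortVariant):
            raise TypeError(f"malformed variant at row {i}: {v!r}")
        for name in active:
            if not rules[name](v, cfg):
                removed[name] += 1
                break
        else:
            kept.append(v)
    return kept, FilterTrace(n_input=n_input, kept=len(kept), removed_by_rule=removed)


def read_variant_table(path, dataset: str = "WES", sample: str = "") -> List[ShortVariant]:
    """Read an annotated variant TSV into ShortVariant objects.

    Expected columns: chrom, pos (0-based), ref, alt, region_class,
    exonic_function, af1, af2, af3 (blank = absent), qual, depth, vaf,
    sor, gene, filters (';'-separated).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    variants = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            variants.append(
                ShortVariant(
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    ref=row.ref,
                    alt=row.alt,
                    region_class=row.region_class,
                    exonic_function=row.exonic_function,
                    pop_af=tuple(
                        None if pd.isna(v) else float(v)
                        for v in (row.af1, row.af2, row.af3)
                    ),
                    qual=float(row.qual),
                    depth=int(row.depth),
                    vaf=float(row.vaf),
                    sor=float(row.sor),
                    gene=str(row.gene) if not pd.isna(row.gene) else "",
                    sample=sample,
                    dataset=dataset,
                    filters=frozenset(str(row.filters).split(";")),
                )
            )
        except (ValueError, AttributeError) as exc:
            raise ValueError(f"malformed variant row {i}: {exc}") from exc
    return variants


def three_way_overlap(
    a: Iterable[ShortVariant],
    b: Iterable[ShortVariant],
    c: Iterable[ShortVariant],
) -> dict:
    """Venn-region counts for three variant sets keyed by normalized alleles.

    Returns the seven exclusive region counts
    {"a_only","b_only","c_only","ab","ac","bc","abc"}; they partition the
    union of the three keyed sets.
    """
    ka = {v.normalized_key() for v in a}
    kb = {v.normalized_key() for v in b}
    kc = {v.normalized_key() for v in c}
    return {
        "a_only": len(ka - kb - kc),
        "b_only": len(kb - ka - kc),
        "c_only": len(kc - ka - kb),
        "ab": len((ka & kb) - kc),
        "ac": len((ka & kc) - kb),
        "bc": len((kb & kc) - ka),
        "abc": len(ka & kb & kc),
    }


def driver_gene_matrix(
    variants_by_group: dict,
    genes: Sequence[str] = DEFAULT_DRIVER_GENES,
) -> pd.DataFrame:
    """Presence/absence matrix of driver-gene mutations.

    ``variants_by_group`` maps (sample, dataset) -> list of kept
    variants. Rows are the (sample, dataset) pairs, columns the gene
    panel; a cell is 1 iff at least one variant in that gene was kept
    for that pair. Dataset labels must be known.
    """
    rows = {}
    for (sample, dataset), variants in variants_by_group.items():
        if dataset not in DATASET_LABELS:
            raise ValueError(
                f"unknown dataset label {dataset!r}; expected one of {DATASET_LABELS}"
            )
        present = {g: 0 for g in genes}
        for v in variants:
            if v.gene in present:
                present[v.gene] = 1
        rows[(sample, dataset)] = present
    if not rows:
        index = pd.MultiIndex.from_arrays([[], []], names=["sample", "dataset"])
        return pd.DataFrame(columns=list(genes), index=index, dtype=int)
    index = pd.MultiIndex.from_tuples(rows.keys(), names=["sample", "dataset"])
    return pd.DataFrame(list(rows.values()), index=index, columns=list(genes)).astype(int)
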