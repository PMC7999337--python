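"""End-to-end orchestration: configuration, stage running, report bundle.

``run_pipeline`` wires the stages together: read and pair the callsets,
tabulate type compositions, compute pairwise concordance, score the
clinical cytogenetic panel, evaluate ROC/AUC against a truth table,
annotate hotspot burdens, and run the short-variant cascade. Stages with
missing inputs are skipped with an explicit notice; every produced table
is written as TSV with a JSON mirror where the structure warrants it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from svconcord import __version__
from svconcord.concordance import (
    MatchConfig,
    match_callsets,
    match_translocations,
    type_composition,
)
from svconcord.cytogenetics import build_event_panel, build_prediction_matrix
from svconcord.hotspots import annotate_hotspots, cohort_summary, hotspot_counts
from svconcord.io import (
    SVCallset,
    pair_breakends,
    read_arm_map,
    read_hotspot_catalog,
    read_sv_vcf,
    read_truth_table,
)
from svconcord.roc import roc_curve
from svconcord.short_variants import (
    FilterConfig,
    apply_filter_cascade,
    driver_gene_matrix,
    read_variant_table,
    three_way_overlap,
)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and input id."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths and parameters for a full pipeline run.

    vcfs : list of (sample, method, path) triples.
    variant_tables : list of (sample, dataset, path) triples for the
        short-variant stage.
    """

    arms_path: str
    vcfs: Sequence[tuple] = ()
    truth_path: Optional[str] = None
    hotspot_path: Optional[str] = None
    variant_tables: Sequence[tuple] = ()
    match: MatchConfig = field(default_factory=MatchConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    pass_only: bool = True
    min_sv_size: int = 0
    n_boot: int = 2000
    seed: int = 0
    out_dir: str = "svconcord_out"

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "arms": str(self.arms_path),
                "vcfs": [list(map(str, v)) for v in self.vcfs],
                "truth": str(self.truth_path),
                "hotspots": str(self.hotspot_path),
                "tables": [list(map(str, v)) for v in self.variant_tables],
                "fraction": self.match.fraction,
                "reciprocal": self.match.reciprocal,
                "w": self.match.translocation_window,
                "pass_only": self.pass_only,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage whose inputs are configured; write the report bundle.

    Returns a summary dict (also written as ``manifest.json``) recording
    the package version, seed, config hash, the stages run or skipped,
    and the paths of every output file. Outputs are deterministic for a
    fixed config and seed. Existing files in the output directory are
    never silently overwritten: a populated manifest aborts the run.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        raise StageError("setup", f"output manifest {manifest_path} already exists")

    manifest = {
        "tool": "svconcord",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
        "outputs": [],
    }

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest["outputs"].append(str(path))

    arms = read_arm_map(config.arms_path)

    # -- stage: read + pair ------------------------------------------------
    callsets = []
    for sample, method, path in config.vcfs:
        try:
            callsets.append(pair_breakends(read_sv_vcf(path, sample, method)))
        except Exception as exc:
            raise StageError("read_sv_vcf", f"{sample}/{method} ({path}): {exc}") from exc
    manifest["stages"]["read"] = {"n_callsets": len(callsets)}

    # -- stage: composition ------------------------------------------------
    if callsets:
        rows = []
        for cs in callsets:
            comp = type_composition(cs)
            rows.append({"sample": cs.sample, "method": cs.method,
                         "n_calls": cs.n_calls(), **comp})
        emit("composition.tsv",
             lambda p: pd.DataFrame(rows).to_csv(p, sep="\t", index=False))
        manifest["stages"]["composition"] = {"n_rows": len(rows)}

    # -- stage: concordance ------------------------------------------------
    by_sample: dict = {}
    for cs in callsets:
        by_sample.setdefault(cs.sample, []).append(cs)
    conc_frames, tr_rows = [], []
    for sample, group in sorted(by_sample.items()):
        if len(group) != 2:
            continue
        a, b = sorted(group, key=lambda c: c.method)
        table = match_callsets(a, b, config.match)
        conc_frames.append(table.to_frame().assign(sample=sample))
        tr = match_translocations(a, b, config.match)
        tr_rows.append({"sample": sample, "method_a": a.method,
                        "method_b": b.method, "svtype": "BND", **tr})
    if conc_frames:
        conc = pd.concat(conc_frames, ignore_index=True)
        emit("concordance.tsv", lambda p: conc.to_csv(p, sep="\t", index=False))
        emit("translocation_concordance.tsv",
             lambda p: pd.DataFrame(tr_rows).to_csv(p, sep="\t", index=False))
        manifest["stages"]["concordance"] = {"n_sample_pairs": len(conc_frames)}
    else:
        manifest["stages"]["concordance"] = "skipped: no sample with two callsets"

    # -- stage: cytogenetics -------------------------------------------
    matrices = {}
    if callsets:
        panel = build_event_panel(arms, min_sv_size=config.min_sv_size)
        matrices = build_prediction_matrix(callsets, panel, pass_only=config.pass_only)
        for method, pm in sorted(matrices.items()):
            emit(f"predictions_{_slug(method)}.tsv",
                 lambda p, pm=pm: pm.table.to_csv(p, sep="\t"))
        manifest["stages"]["cytogenetics"] = {"methods": sorted(matrices)}

    # -- stage: ROC ----------------------------------------------------
    if config.truth_path and matrices:
        truth = read_truth_table(config.truth_path)
        roc_summary = {}
        for method, pm in sorted(matrices.items()):
            try:
                res = roc_curve(pm, truth, n_boot=config.n_boot, seed=config.seed)
            except ValueError as exc:
                raise StageError("roc", f"method {method}: {exc}") from exc
            curve = pd.DataFrame(
                {"threshold": res.thresholds, "tpr": res.tpr, "fpr": res.fpr}
            )
            emit(f"roc_{_slug(method)}.tsv",
                 lambda p, c=curve: c.to_csv(p, sep="\t", index=False))
            roc_summary[method] = {
                "auc": res.auc, "ci_low": res.ci_low, "ci_high": res.ci_high,
                "P": res.P, "N": res.N,
            }
        emit("roc_summary.json",
             lambda p: p.write_text(json.dumps(roc_summary, indent=2) + "\n"))
        manifest["stages"]["roc"] = roc_summary
    else:
        manifest["stages"]["roc"] = "skipped: no truth table configured"

    # -- stage: hotspots -------------------------------------------------
    if config.hotspot_path and callsets:
        catalog = read_hotspot_catalog(config.hotspot_path)
        frames, summary_rows = [], []
        totals_by_method: dict = {}
        for cs in callsets:
            hits = annotate_hotspots(cs, catalog, pass_only=config.pass_only)
            frames.append(hits.to_frame().assign(method=cs.method))
            counts = hotspot_counts(hits)
            summary_rows.append({"sample": cs.sample, "method": cs.method,
                                 "total": counts["total"], **counts["counts"]})
            totals_by_method.setdefault(cs.method, []).append(counts["total"])
        emit("hotspot_hits.tsv",
             lambda p: pd.concat(frames, ignore_index=True).to_csv(p, sep="\t", index=False))
        emit("hotspot_counts.tsv",
             lambda p: pd.DataFrame(summary_rows).to_csv(p, sep="\t", index=False))
        cohort = {m: cohort_summary(t) for m, t in sorted(totals_by_method.items())}
        emit("hotspot_cohort.json",
             lambda p: p.write_text(json.dumps(cohort, indent=2) + "\n"))
        manifest["stages"]["hotspots"] = cohort
    else:
        manifest["stages"]["hotspots"] = "skipped: no hotspot catalog configured"

    # -- stage: short variants ----------------------------------------
    if config.variant_tables:
        kept_by_group, traces = {}, {}
        for sample, dataset, path in config.variant_tables:
            variants = read_variant_table(path, dataset=dataset, sample=sample)
            kept, trace = apply_filter_cascade(variants, config.filters)
            kept_by_group[(sample, dataset)] = kept
            traces[f"{sample}/{dataset}"] = {
                "n_input": trace.n_input, "kept": trace.kept,
                "removed_by_rule": trace.removed_by_rule,
            }
        emit("filter_traces.json",
             lambda p: p.write_text(json.dumps(traces, indent=2) + "\n"))
        datasets = sorted({d for _, d in kept_by_group})
        if len(datasets) == 3:
            venn = {}
            samples = sorted({s for s, _ in kept_by_group})
            for s in samples:
                sets = [kept_by_group.get((s, d), []) for d in datasets]
                venn[s] = three_way_overlap(*sets)
            emit("venn_counts.json",
                 lambda p: p.write_text(json.dumps(
                     {"datasets": datasets, "per_sample": venn}, indent=2) + "\n"))
        matrix = driver_gene_matrix(kept_by_group)
        emit("driver_matrix.tsv", lambda p: matrix.to_csv(p, sep="\t"))
        manifest["stages"]["short_variants"] = {"groups": len(kept_by_group)}
    else:
        manifest["stages"]["short_variants"] = "skipped: no variant tables configured"

    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    manifest["outputs"].append(str(manifest_path))
    return manifest


def _slug(text: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in text)
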