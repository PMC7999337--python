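"""Shared fixtures: arm maps, record builders, random callset generators."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from svconcord.cytogenetics import PredictionMatrix, build_event_panel
from svconcord.io import (
    Breakend,
    BndOrientation,
    GenomicInterval,
    SVCallset,
    SVRecord,
    TranslocationEvent,
    TruthTable,
)
from svconcord.synthetic import synthetic_arm_map


@pytest.fixture(scope="session")
def arms():
    return synthetic_arm_map()


@pytest.fixture(scope="session")
def panel(arms):
    return build_event_panel(arms)


def make_record(
    record_id="r1",
    svtype="DEL",
    chrom="1",
    start=100,
    end=200,
    svlen=None,
    filters=("PASS",),
    sample="S01",
    method="wes",
    quality=100.0,
):
    """An interval SVRecord with sensible defaults."""
    if svlen is None:
        svlen = (start - end) if svtype == "DEL" else (end - start)
    return SVRecord(
        record_id=record_id,
        sample=sample,
        method=method,
        svtype=svtype,
        interval=GenomicInterval(chrom, start, end),
        svlen=svlen,
        quality=quality,
        filters=frozenset(filters),
    )


def make_bnd_pair(
    base_id="bnd1",
    chrom_a="14",
    pos_a=50_000_000,
    chrom_b="4",
    pos_b=10_000_000,
    filters=("PASS",),
    sample="S01",
    method="wes",
    mutual=True,
):
    """Two BND records referencing each other via MATEID (or dangling)."""
    id_a, id_b = f"{base_id}:0", f"{base_id}:1"
    be_a = Breakend(chrom_a, pos_a, BndOrientation.T_RIGHT_FWD)
    be_b = Breakend(chrom_b, pos_b, BndOrientation.LEFT_FWD)
    rec_a = SVRecord(
        record_id=id_a, sample=sample, method=method, svtype="BND",
        filters=frozenset(filters), mate_id=id_b, breakend=be_a,
        mate_breakend=Breakend(chrom_b, pos_b, BndOrientation.T_RIGHT_FWD),
    )
    rec_b = SVRecord(
        record_id=id_b, sample=sample, method=method, svtype="BND",
        filters=frozenset(filters), mate_id=id_a if mutual else "missing",
        breakend=be_b,
        mate_breakend=Breakend(chrom_a, pos_a, BndOrientation.LEFT_FWD),
    )
    return rec_a, rec_b


def make_event(chrom_a="14", pos_a=50_000_000, chrom_b="4", pos_b=10_000_000,
               filters=("PASS",), ids=("x:0", "x:1")):
    return TranslocationEvent(
        breakend_a=Breakend(chrom_a, pos_a, BndOrientation.T_RIGHT_FWD),
        breakend_b=Breakend(chrom_b, pos_b, BndOrientation.LEFT_FWD),
        source_ids=tuple(ids),
        filters=frozenset(filters),
    )


def random_interval_callset(rng, n, sample="S01", method="m", chroms=("1", "2", "3"),
                            span=1_000_000, max_len=5_000):
    """A callset of random interval records across a few chromosomes."""
    records = []
    for i in range(n):
        svtype = ("DEL", "DUP", "INV", "INS")[rng.integers(0, 4)]
        chrom = chroms[rng.integers(0, len(chroms))]
        if svtype == "INS":
            start = int(rng.integers(0, span))
            end = start + 1
            svlen = int(rng.integers(50, 500))
        else:
            start = int(rng.integers(0, span))
            length = int(rng.integers(1, max_len))
            end = start + length
            svlen = -length if svtype == "DEL" else length
        records.append(
            make_record(record_id=f"{method}:{i}", svtype=svtype, chrom=chrom,
                        start=start, end=end, svlen=svlen,
                        sample=sample, method=method)
        )
    return SVCallset(sample=sample, method=method, records=records)


def vectors_as_grid(scores, labels):
    """Wrap flat score/label vectors as a single-event prediction/truth grid."""
    samples = [f"S{i:03d}" for i in range(len(scores))]
    pred = PredictionMatrix(
        table=pd.DataFrame({"E": list(scores)}, index=samples), method="m"
    )
    truth = TruthTable(pd.DataFrame({"E": [int(l) for l in labels]}, index=samples))
    return pred, truth


def mannwhitney_auc(scores, labels):
    """Pair-enumeration concordance probability: (wins + half ties) / (P*N)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))
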