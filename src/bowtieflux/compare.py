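"""Agreement diagnostics between the FBA and GBA bow-tie partitions."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .bowtie import CLASSES, BowTiePartition, ConnectivityTable

logger = logging.getLogger(__name__)

__all__ = ["ComparisonReport", "confusion_matrix", "gsc_diff", "central_metabolite_report"]

DIFF_LABELS = ("produced_only", "consumed_only", "neither")


@dataclass
class ComparisonReport:
    """4x4 confusion matrix between the two classifications plus the
    GSC disagreement sets."""

    matrix: pd.DataFrame          # rows f-classes, columns g-classes
    nodes: frozenset[str]
    gsc_gba_only: frozenset[str]  # gGSC \ fGSC
    gsc_fba_only: frozenset[str]  # fGSC \ gGSC
    diff_labels: dict[str, str]   # member of gGSC\fGSC -> subcategory

    @property
    def n_agree(self) -> int:
        return int(sum(self.matrix.iloc[i, i] for i in range(len(CLASSES))))

    @property
    def agreement(self) -> float:
        return self.n_agree / len(self.nodes)

    def write_tsv(self, path: str | Path) -> None:
        self.matrix.to_csv(path, sep="\t", index_label="fba\\gba")


def confusion_matrix(
    fba: BowTiePartition, gba: BowTiePartition
) -> tuple[ComparisonReport, pd.DataFrame]:
    """Cross-tabulate the two partitions over their common node set.

    Returns the report and a per-metabolite frame (fba class, gba
    class).  Partially overlapping node sets are intersected with a
    warning; disjoint ones raise.
    """
    common = fba.nodes & gba.nodes
    if not common:
        raise ValueError("partitions share no nodes")
    dropped = (fba.nodes | gba.nodes) - common
    if dropped:
        logger.warning("comparison restricted to %d common nodes (%d dropped)",
                       len(common), len(dropped))
    rows = [
        {"metabolite": mid, "fba": fba.class_of(mid), "gba": gba.class_of(mid)}
        for mid in sorted(common)
    ]
    per_met = pd.DataFrame.from_records(rows).set_index("metabolite")
    matrix = pd.crosstab(per_met["fba"], per_met["gba"]).reindex(
        index=list(CLASSES), columns=list(CLASSES), fill_value=0
    )
    matrix.index = [f"f{c}" for c in CLASSES]
    matrix.columns = [f"g{c}" for c in CLASSES]
    report = ComparisonReport(
        matrix=matrix,
        nodes=frozenset(common),
        gsc_gba_only=frozenset(gba["GSC"] & common - fba["GSC"]),
        gsc_fba_only=frozenset(fba["GSC"] & common - gba["GSC"]),
        diff_labels={},
    )
    return report, per_met


def gsc_diff(
    report: ComparisonReport, table: ConnectivityTable
) -> dict[str, str]:
    """Label each member of gGSC \\ fGSC by its FBA connectivity:
    produced_only / consumed_only / neither (by the same thresholded
    flags that produced the FBA partition)."""
    prod = table.producible()
    cons = table.consumable()
    labels: dict[str, str] = {}
    for mid in sorted(report.gsc_gba_only):
        p = bool(prod.get(mid, False))
        c = bool(cons.get(mid, False))
        if p and c:  # pragma: no cover - would belong to fGSC
            raise AssertionError(f"{mid} produced+consumed yet not in fGSC")
        labels[mid] = "produced_only" if p else ("consumed_only" if c else "neither")
    report.diff_labels = labels
    return labels


def central_metabolite_report(
    partitions: Mapping[str, BowTiePartition],
    central: Sequence[tuple[str, Sequence[str]]],
) -> pd.DataFrame:
    """Presence of central metabolites in the GSCs of a model batch.

    ``central`` lists (display name, candidate species ids); a
    metabolite counts as present in a model when any candidate id is in
    that model's GSC.  Ids absent from a model count as absent.
    """
    records = []
    for name, ids in central:
        n = 0
        for model_name, part in partitions.items():
            if any(mid in part["GSC"] for mid in ids):
                n += 1
        records.append({"name": name, "ids": ";".join(ids), "n_models": n})
    return pd.DataFrame.from_records(records).set_index("name")
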