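"""CNV filtering, per-sample clinical class and diagnostic yield.

Two filter regimes are supported: the conventional clinical thresholds
(losses > 100 Kbp, gains > 150 Kbp, >= 50 markers) and the research
thresholds used for gene discovery (> 10 Kbp either type, >= 10
markers).  Classification labels (benign / VUS / LPCNV / PCNV) are input
annotations produced by external curation — never computed here.  A
sample's result is the class of its most clinically relevant CNV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .genome import GenomicInterval
from .segment_io import SampleRecord, SegmentRow

__all__ = [
    "CnvCall",
    "CLASS_PRECEDENCE",
    "filter_cnvs",
    "most_relevant_class",
    "diagnostic_yield",
    "class_metric_summary",
]

#: Clinical relevance precedence, most relevant first.
CLASS_PRECEDENCE = ("PCNV", "LPCNV", "VUS", "benign")

RESEARCH_FILTER = {"loss_kbp": 10.0, "gain_kbp": 10.0, "min_markers": 10}
CLINICAL_FILTER = {"loss_kbp": 100.0, "gain_kbp": 150.0, "min_markers": 50}


@dataclass(frozen=True)
class CnvCall:
    sample_id: str
    interval: GenomicInterval
    cnv_type: str  # gain | loss
    copy_number: int | None = None
    marker_count: int | None = None
    classification: str = "unclassified"
    gene_count: int | None = None
    omim_gene_count: int | None = None

    @property
    def size_kbp(self) -> float:
        return self.interval.length_bp / 1e3

    @classmethod
    def from_segment_row(cls, row: SegmentRow, classification: str = "unclassified") -> "CnvCall":
        return cls(
            sample_id=row.sample_id,
            interval=row.interval,
            cnv_type="gain" if row.seg_type == "Gain" else "loss",
            copy_number=row.copy_number,
            marker_count=row.marker_count,
            classification=classification,
        )


def filter_cnvs(
    calls: Iterable[CnvCall], mode: str = "research"
) -> tuple[list[CnvCall], list[str]]:
    """Apply size and marker-count filters; returns (kept, diagnostics).

    Size thresholds are strict (>); the marker minimum is inclusive.  A
    call with unknown marker count cannot satisfy the marker criterion
    and is rejected with a diagnostic.
    """
    if mode not in ("research", "clinical"):
        raise ValueError(f"mode must be 'research' or 'clinical', got {mode!r}")
    rules = RESEARCH_FILTER if mode == "research" else CLINICAL_FILTER
    kept, diagnostics = [], []
    for call in calls:
        threshold = rules["gain_kbp"] if call.cnv_type == "gain" else rules["loss_kbp"]
        if call.marker_count is None:
            diagnostics.append(
                f"{call.sample_id} {call.cnv_type} at {call.interval.chromosome}:"
                f"{call.interval.start}: unknown marker count, rejected in {mode} mode"
            )
            continue
        if call.size_kbp > threshold and call.marker_count >= rules["min_markers"]:
            kept.append(call)
    return kept, diagnostics


def most_relevant_class(calls: Iterable[CnvCall]) -> str:
    """The sample-level class: PCNV > LPCNV > VUS > benign > none."""
    present = {c.classification for c in calls}
    for cls in CLASS_PRECEDENCE:
        if cls in present:
            return cls
    return "none"


def diagnostic_yield(cohort: Iterable[SampleRecord]) -> dict:
    """Cohort class fractions: pathogenic yield and inconclusive (VUS/LPCNV) rate."""
    classes = [most_relevant_class(s.cnv_calls) for s in cohort]
    n = len(classes)
    counts = {cls: classes.count(cls) for cls in (*CLASS_PRECEDENCE, "none")}
    return {
        "n": n,
        "counts": counts,
        "pathogenic_count": counts["PCNV"],
        "pathogenic_fraction": counts["PCNV"] / n if n else 0.0,
        "inconclusive_count": counts["VUS"] + counts["LPCNV"],
        "inconclusive_fraction": (counts["VUS"] + counts["LPCNV"]) / n if n else 0.0,
    }


def class_metric_summary(
    calls: Iterable[CnvCall], sd_for_singletons: str = "nan"
) -> pd.DataFrame:
    """Per-class mean, SD, min, max of size and gene counts.

    Missing metrics are excluded pairwise; the count column reports how
    many calls contributed to each metric.  ``sd_for_singletons``
    selects whether a one-call class reports SD as NaN or 0.
    """
    rows = []
    data = list(calls)
    by_class: dict[str, list[CnvCall]] = {}
    for call in data:
        by_class.setdefault(call.classification, []).append(call)
    for cls, items in sorted(by_class.items()):
        for metric, getter in (
            ("size_kbp", lambda c: c.size_kbp),
            ("gene_count", lambda c: c.gene_count),
            ("omim_gene_count", lambda c: c.omim_gene_count),
        ):
            values = [getter(c) for c in items if getter(c) is not None]
            if not values:
                continue
            if len(values) > 1:
                sd = float(np.std(values, ddof=1))
            else:
                sd = math.nan if sd_for_singletons == "nan" else 0.0
            rows.append(
                {
                    "classification": cls,
                    "metric": metric,
                    "n": len(values),
                    "mean": float(np.mean(values)),
                    "sd": sd,
                    "min": float(min(values)),
                    "max": float(max(values)),
                }
            )
    return pd.DataFrame(rows, columns=["classification", "metric", "n", "mean", "sd", "min", "max"])
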