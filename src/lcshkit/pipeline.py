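"""End-to-end orchestration: parse -> mask -> LCSH -> consanguinity ->
UPD -> common regions -> CNV yield -> association.

One call produces a report bundle plus a manifest with input digests
and per-stage record counts; identical inputs and configuration
reproduce identical digests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cnv import diagnostic_yield, filter_cnvs
from .common_regions import delineate_common_regions
from .cohort_stats import phenotype_association_table
from .consanguinity import cohort_consanguinity_profile, sample_report
from .genome import hg19
from .lcsh import attach_lcsh
from .segment_io import group_cohort, read_phenotype_table, read_segment_table
from .upd import call_upd_candidates, flag_imprinted

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Thresholds for one run; defaults are the standard clinical-analysis values."""

    min_lcsh_mbp: float = 3.0
    hemizygous_overlap_fraction: float = 0.5
    upd_over_threshold_mbp: float = 5.0
    upd_min_total_mbp: float = 10.0
    common_region_min_frequency: float = 0.05
    cnv_filter_mode: str = "research"

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**known)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    segments_path: str | Path,
    phenotypes_path: str | Path | None = None,
    out_dir: str | Path = "lcshkit_out",
    config: PipelineConfig | None = None,
) -> dict:
    """Run every stage and write the report bundle; returns the manifest."""
    config = config or PipelineConfig()
    build = hg19()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    segments_path = Path(segments_path)

    parsed = read_segment_table(segments_path, build=build)
    phenotypes = read_phenotype_table(phenotypes_path) if phenotypes_path else {}
    cohort, orphan_notes = group_cohort(parsed.rows, phenotypes, build)
    n_loh_rows = sum(1 for r in parsed.rows if r.seg_type == "LOH")
    for sample in cohort:
        attach_lcsh(
            sample,
            min_size_mbp=config.min_lcsh_mbp,
            hemizygous_overlap_fraction=config.hemizygous_overlap_fraction,
        )
    n_lcsh = sum(len(s.lcsh_segments) for s in cohort)
    n_masked = sum(
        1 for s in cohort for seg in s.lcsh_segments if seg.masked_reason != "none"
    )

    # UPD must be known before the consanguinity profile: a single-chromosome
    # pattern is excluded from the cohort inbreeding fractions
    upd_lists = {
        s.sample_id: call_upd_candidates(
            s,
            min_total_mbp=config.upd_min_total_mbp,
            over_threshold_mbp=config.upd_over_threshold_mbp,
        )
        for s in cohort
    }
    upd_rows = []
    for sample in cohort:
        for cand in upd_lists[sample.sample_id]:
            imprinted, note = flag_imprinted(cand)
            upd_rows.append(
                {
                    "sample_id": cand.sample_id,
                    "chromosome": cand.chromosome,
                    "n_segments": len(cand.segments),
                    "total_mbp": round(cand.total_mbp, 1),
                    "rule": cand.rule,
                    "imprinted": imprinted,
                    "imprinting_note": note,
                    "segments": ";".join(
                        f"{s.interval.chromosome}:{s.interval.start}-{s.interval.end}"
                        for s in cand.segments
                    ),
                }
            )
    upd_frame = pd.DataFrame(
        upd_rows,
        columns=[
            "sample_id", "chromosome", "n_segments", "total_mbp",
            "rule", "imprinted", "imprinting_note", "segments",
        ],
    )
    upd_frame.to_csv(out / "upd_candidates.tsv", sep="\t", index=False)

    reports = [
        sample_report(s, upd_excluded=bool(upd_lists[s.sample_id]))
        for s in cohort
    ]
    consang_frame = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in reports],
            "sum_mbp": [round(r.sum_autosomal_lcsh_mbp, 1) for r in reports],
            "F": [round(r.f_hat, 3) for r in reports],
            "kinship_class": [r.kinship_class for r in reports],
            "expected_ibd_percent": [r.expected_ibd_percent for r in reports],
            "upd_excluded": [r.upd_excluded for r in reports],
        }
    )
    consang_frame.to_csv(out / "consanguinity.tsv", sep="\t", index=False)
    profile = cohort_consanguinity_profile(reports)

    regions = (
        delineate_common_regions(cohort, build, config.common_region_min_frequency)
        if cohort
        else []
    )
    regions_frame = pd.DataFrame(
        {
            "frequency_percent": [round(100 * r.frequency, 1) for r in regions],
            "band_span": [r.band_span for r in regions],
            "start": [r.delineated_interval.start for r in regions],
            "end": [r.delineated_interval.end for r in regions],
            "size_mbp": [round(r.size_mbp, 3) for r in regions],
        }
    )
    regions_frame.to_csv(out / "common_regions.tsv", sep="\t", index=False)

    all_cnvs = [c for s in cohort for c in s.cnv_calls]
    kept_cnvs, cnv_diags = filter_cnvs(all_cnvs, mode=config.cnv_filter_mode)
    kept_ids = {id(c) for c in kept_cnvs}
    for sample in cohort:
        sample.cnv_calls = [c for c in sample.cnv_calls if id(c) in kept_ids]
    yield_summary = diagnostic_yield(cohort)

    association = phenotype_association_table(cohort)
    association.to_csv(out / "association.tsv", sep="\t", index=False)

    summary = {
        "diagnostic_yield": yield_summary,
        "consanguinity_profile": profile,
        "upd_candidates": len(upd_rows),
        "upd_rate": len(upd_rows) / len(cohort) if cohort else 0.0,
        "common_regions": regions_frame.to_dict(orient="records"),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))

    manifest = {
        "tool_version": __version__,
        "config": asdict(config),
        "inputs": {
            segments_path.name: _sha256(segments_path),
            **(
                {Path(phenotypes_path).name: _sha256(Path(phenotypes_path))}
                if phenotypes_path
                else {}
            ),
        },
        "counts": {
            "segment_rows": len(parsed.rows),
            "parse_errors": len(parsed.errors),
            "samples": len(cohort),
            "loh_rows": n_loh_rows,
            "lcsh_ge_threshold": n_lcsh,
            "lcsh_masked": n_masked,
            "lcsh_analyzable": n_lcsh - n_masked,
            "upd_candidates": len(upd_rows),
            "cnv_calls_filtered": len(kept_cnvs),
            "common_regions": len(regions),
        },
        "warnings": parsed.errors + orphan_notes + cnv_diags,
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.glob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
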