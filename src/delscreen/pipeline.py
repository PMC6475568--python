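"""End-to-end driver: profiles → variant flagging → paired-end validation → report."""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import pysam

from . import dgv, pem, profiles, report
from .profiles import BinnedTrack, SuspiciousRegion, ThresholdSet

__all__ = ["PipelineConfig", "PipelineResult", "scan_tracks", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs for one end-to-end run, with the screen's defaults."""

    bin_size: int = 100
    min_length: int = 500
    loess_window: int = profiles.DEFAULT_LOESS_WINDOW
    gc_tail_fraction: float = 0.05
    map_right_area: float = 0.20
    #: When set, use this mappability threshold instead of deriving it from
    #: the track's own distribution (the quantile rule needs a broad
    #: sub-unity value population to be meaningful).
    fixed_th3: float | None = 0.92
    flag_f_threshold: float = 0.9
    validation: pem.ValidationConfig = field(default_factory=pem.ValidationConfig)
    filter: dgv.FilterConfig = field(default_factory=dgv.FilterConfig)


def scan_tracks(
    gc_tracks: dict[str, BinnedTrack],
    map_tracks: dict[str, BinnedTrack],
    config: PipelineConfig = PipelineConfig(),
) -> tuple[ThresholdSet, list[SuspiciousRegion]]:
    """Select thresholds and segment every chromosome into suspicious regions.

    GC thresholds come from the pooled raw GC distribution (tail quantiles);
    the mappability threshold is either ``fixed_th3`` or the quantile of the
    pooled sub-unity mappability values.
    """
    import numpy as np

    gc_values = np.concatenate([t.values for t in gc_tracks.values()])
    th1, th2 = profiles.select_gc_thresholds(gc_values, config.gc_tail_fraction)
    if config.fixed_th3 is not None:
        th3 = config.fixed_th3
    else:
        map_values = np.concatenate([t.values for t in map_tracks.values()])
        th3 = profiles.select_mappability_threshold(map_values, config.map_right_area)
    thresholds = ThresholdSet(th1, th2, th3)
    logger.info("thresholds: th1=%.4f th2=%.4f th3=%.4f", th1, th2, th3)

    regions: list[SuspiciousRegion] = []
    for chrom, track in sorted(gc_tracks.items()):
        sm = profiles.loess_smooth(track, config.loess_window)
        regions += profiles.segment_suspicious(
            sm, track, thresholds, "gc", config.min_length
        )
    for chrom, track in sorted(map_tracks.items()):
        sm = profiles.loess_smooth(track, config.loess_window)
        regions += profiles.segment_suspicious(
            sm, track, thresholds, "mappability", config.min_length
        )
    return thresholds, regions


@dataclass
class PipelineResult:
    thresholds: ThresholdSet
    suspicious_regions: list[SuspiciousRegion]
    n_variants_read: int
    n_after_filter: int
    n_after_merge: int
    flagged: list
    results: list[pem.ValidationResult]
    summary: report.SummaryStats


def run_pipeline(
    gc_tracks: dict[str, BinnedTrack],
    map_tracks: dict[str, BinnedTrack],
    variants_tsv: str,
    manifest: dict[str, str],
    config: PipelineConfig = PipelineConfig(),
    out_dir: str | None = None,
) -> PipelineResult:
    """Run the full screen and (optionally) write its artifacts to *out_dir*."""
    thresholds, regions = scan_tracks(gc_tracks, map_tracks, config)
    merged = profiles.build_suspicious_regions(
        [r for r in regions if r.cause in ("gc_low", "gc_high")],
        [r for r in regions if r.cause == "low_mappability"],
    )

    variants = dgv.read_dgv_table(variants_tsv)
    filtered = dgv.filter_variants(variants, config.filter)
    deduped = dgv.merge_duplicates(filtered)
    flagged = dgv.flag_suspicious(
        deduped, merged, config.flag_f_threshold, causes=regions
    )
    logger.info(
        "variants: %d read, %d filtered, %d after dedup, %d flagged suspicious",
        len(variants), len(filtered), len(deduped), len(flagged),
    )

    results = pem.validate_all(flagged, manifest, config.validation)

    chrom_lengths: dict[str, int] = {}
    for path in set(manifest.values()):
        with pysam.AlignmentFile(path) as aln:
            for name, length in zip(aln.references, aln.lengths):
                chrom_lengths[name] = length
    summary = report.summarize(results, chrom_lengths)

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        from .intervals import write_bed

        write_bed(merged, os.path.join(out_dir, "suspicious_regions.bed"))
        with open(os.path.join(out_dir, "thresholds.txt"), "w") as fh:
            fh.write(
                f"th1\t{thresholds.th1:.6f}\nth2\t{thresholds.th2:.6f}\n"
                f"th3\t{thresholds.th3:.6f}\n"
            )
        dgv.write_flagged_tsv(flagged, os.path.join(out_dir, "suspicious_variants.tsv"))
        report.write_results_spreadsheet(
            results, os.path.join(out_dir, "validation_results.tsv")
        )
        report.write_summary(
            summary,
            os.path.join(out_dir, "summary.tsv"),
            os.path.join(out_dir, "summary.json"),
        )

    return PipelineResult(
        thresholds=thresholds,
        suspicious_regions=regions,
        n_variants_read=len(variants),
        n_after_filter=len(filtered),
        n_after_merge=len(deduped),
        flagged=flagged,
        results=results,
        summary=summary,
    )
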