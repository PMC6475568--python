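"""Truth-labelled synthetic inputs: profile tracks, alignments, variant tables.

The simulator plants two kinds of features on one synthetic chromosome:

* **true deletions** — homozygous: fragments straddling the deletion have
  the deleted bases excised, so their mapped mates are pushed apart on the
  reference and the pair span covers the deletion; no read starts inside.
* **bias artifacts** — coverage valleys with NO discordant support:
  concordant fragments are thinned to a fraction of normal coverage, and
  the GC or mappability track is driven beyond threshold over the window.

All outputs (tracks, a sorted+indexed BAM, a DGV-style variant table, a
truth table, and a sample manifest) are deterministic functions of the
config, including its seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import pysam

from .intervals import GenomicInterval
from .profiles import BinnedTrack, write_bedgraph

__all__ = [
    "SimConfig",
    "SimTruth",
    "TruthRecord",
    "plan_truth",
    "simulate_profiles",
    "simulate_read_pairs",
    "emit_variant_table",
    "write_truth_table",
    "read_truth_table",
    "simulate",
    "SimOutputs",
]

Cause = Literal["gc_low", "gc_high", "low_mappability"]
_ARTIFACT_CAUSES: tuple[Cause, ...] = ("gc_low", "low_mappability", "gc_high")


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    chrom_name: str = "chrSim"
    chrom_length: int = 2_000_000
    bin_size: int = 100
    read_length: int = 100
    insert_mean: float = 500.0
    insert_sd: float = 50.0
    coverage: float = 30.0
    gc_background_mean: float = 0.41
    gc_background_sd: float = 0.05
    map_one_fraction: float = 0.70
    map_zero_fraction: float = 0.0
    map_noise_mean: float = 0.97
    map_noise_sd: float = 0.01
    n_true_deletions: int = 10
    n_bias_artifacts: int = 10
    deletion_size_range: tuple[int, int] = (1500, 8000)
    artifact_size_range: tuple[int, int] = (1500, 8000)
    artifact_coverage_factor: float = 0.2
    artifact_gc: float = 0.15
    artifact_gc_high: float = 0.75
    artifact_mappability: float = 0.85
    bias_true_deletions: bool = False
    n_decoys: int = 5
    sample_name: str = "SIM001"
    study_name: str = "SimStudy et al. 2020"
    min_feature_gap: int = 20_000
    edge_margin: int = 20_000

    def __post_init__(self) -> None:
        for lo, hi in (self.deletion_size_range, self.artifact_size_range):
            if not (500 < lo <= hi < 10_000):
                raise ValueError(
                    "feature sizes must lie strictly inside (500, 10000) so "
                    "implants pass the pipeline's own filters"
                )
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.insert_mean < 2 * self.read_length:
            raise ValueError("insert_mean must be at least twice the read length")
        n = self.n_true_deletions + self.n_bias_artifacts
        if n > 0:
            slot = (self.chrom_length - 2 * self.edge_margin) // n
            need = max(self.deletion_size_range[1], self.artifact_size_range[1])
            if slot < need + self.min_feature_gap:
                raise ValueError(
                    f"chromosome too short for {n} features of up to {need} bp "
                    f"spaced >= {self.min_feature_gap} bp apart"
                )


@dataclass(frozen=True)
class TruthRecord:
    accession: str
    interval: GenomicInterval
    kind: Literal["true_deletion", "bias_artifact"]
    cause: Cause | None
    expected_verdict: Literal["true_positive", "false_positive"]


@dataclass
class SimTruth:
    records: list[TruthRecord]

    @property
    def true_deletions(self) -> list[GenomicInterval]:
        return [r.interval for r in self.records if r.kind == "true_deletion"]

    @property
    def bias_artifacts(self) -> list[TruthRecord]:
        return [r for r in self.records if r.kind == "bias_artifact"]

    def expected_verdict(self, accession: str) -> str:
        for r in self.records:
            if r.accession == accession:
                return r.expected_verdict
        raise KeyError(accession)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _draw_size(rng: np.random.Generator, size_range: tuple[int, int], bin_size: int) -> int:
    lo, hi = size_range
    lo_b = -(-lo // bin_size)  # sizes bin-aligned for clean segment recovery
    hi_b = hi // bin_size
    return int(rng.integers(lo_b, hi_b + 1)) * bin_size


def plan_truth(config: SimConfig) -> SimTruth:
    """Place non-overlapping, well-separated features and assign labels.

    Features are laid out one per equal-width slot (guaranteeing the
    minimum gap), starts are bin-aligned, and the role of each slot
    (deletion vs artifact) is a seeded permutation.
    """
    rng = _rng(config, 0)
    n = config.n_true_deletions + config.n_bias_artifacts
    records: list[TruthRecord] = []
    if n == 0:
        return SimTruth(records)
    roles = ["true_deletion"] * config.n_true_deletions + \
            ["bias_artifact"] * config.n_bias_artifacts
    roles = [roles[i] for i in rng.permutation(n)]
    slot = (config.chrom_length - 2 * config.edge_margin) // n
    i_del = i_art = 0
    for i, role in enumerate(roles):
        if role == "true_deletion":
            size = _draw_size(rng, config.deletion_size_range, config.bin_size)
        else:
            size = _draw_size(rng, config.artifact_size_range, config.bin_size)
        max_off = slot - size - config.min_feature_gap - config.bin_size
        off = int(rng.integers(0, max(1, max_off + 1)))
        start = (config.edge_margin + i * slot + off) \
            // config.bin_size * config.bin_size
        iv = GenomicInterval(config.chrom_name, start, start + size)
        if role == "true_deletion":
            cause = "gc_low" if config.bias_true_deletions else None
            records.append(
                TruthRecord(f"essv{1000000 + i_del}", iv, "true_deletion", cause,
                            "true_positive")
            )
            i_del += 1
        else:
            cause = _ARTIFACT_CAUSES[i_art % len(_ARTIFACT_CAUSES)]
            records.append(
                TruthRecord(f"essv{2000000 + i_art}", iv, "bias_artifact", cause,
                            "false_positive")
            )
            i_art += 1
    return SimTruth(records)


def _bin_slice(iv: GenomicInterval, bin_size: int) -> slice:
    return slice(iv.start // bin_size, -(-iv.end // bin_size))


def simulate_profiles(
    config: SimConfig, truth: SimTruth | None = None
) -> tuple[BinnedTrack, BinnedTrack, SimTruth]:
    """Generate GC and mappability tracks with the planted bias windows.

    Background GC is Gaussian noise around ``gc_background_mean``;
    background mappability is a mix of an exact-1.0 mass, an optional
    exact-0.0 mass, and near-one noise.  Bias-artifact windows (and, when
    ``bias_true_deletions`` is set, true-deletion windows) are overwritten
    with their cause's extreme value.
    """
    if truth is None:
        truth = plan_truth(config)
    rng = _rng(config, 1)
    n_bins = -(-config.chrom_length // config.bin_size)

    gc = rng.normal(config.gc_background_mean, config.gc_background_sd, n_bins)
    u = rng.random(n_bins)
    mp = np.empty(n_bins)
    one = u < config.map_one_fraction
    zero = (~one) & (u < config.map_one_fraction + config.map_zero_fraction)
    rest = ~(one | zero)
    mp[one] = 1.0
    mp[zero] = 0.0
    mp[rest] = np.clip(
        rng.normal(config.map_noise_mean, config.map_noise_sd, int(rest.sum())),
        5e-4, 1.0 - 5e-4,
    )

    for rec in truth.records:
        if rec.cause is None:
            continue
        sl = _bin_slice(rec.interval, config.bin_size)
        width = sl.stop - sl.start
        jitter = rng.normal(0.0, 0.01, width)
        if rec.cause == "gc_low":
            gc[sl] = config.artifact_gc + jitter
        elif rec.cause == "gc_high":
            gc[sl] = config.artifact_gc_high + jitter
        else:
            mp[sl] = config.artifact_mappability + jitter

    gc = np.clip(gc, 0.0, 1.0)
    mp = np.clip(mp, 0.0, 1.0)
    gc_track = BinnedTrack(config.chrom_name, config.bin_size, gc)
    map_track = BinnedTrack(config.chrom_name, config.bin_size, mp)
    return gc_track, map_track, truth


def _donor_map(deletions: list[GenomicInterval], chrom_length: int):
    """Donor→reference coordinate machinery for homozygous excision.

    Returns (donor_length, breakpoints, cumulative_deleted) where
    ``breakpoints`` are donor positions of the excision points and
    ``cumulative_deleted[k]`` is the total deleted length left of the k-th
    breakpoint region.
    """
    dels = sorted(deletions, key=lambda d: d.start)
    lengths = np.array([d.length for d in dels], dtype=np.int64)
    starts = np.array([d.start for d in dels], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(lengths)])
    breakpoints = starts - cum[:-1]
    donor_length = chrom_length - int(lengths.sum()) if len(dels) else chrom_length
    return donor_length, breakpoints, cum


def simulate_read_pairs(config: SimConfig, truth: SimTruth, out_bam: str) -> str:
    """Simulate FR read pairs and write a coordinate-sorted, indexed BAM.

    Fragment count targets ``coverage * chrom_length / (2 * read_length)``;
    fragment lengths are Normal(insert_mean, insert_sd) truncated at twice
    the read length.  Fragments straddling a true deletion are excised
    (mates pushed apart on the reference); fragments whose mates would
    cross an excision point are dropped.  Fragments overlapping a bias
    artifact are thinned to ``artifact_coverage_factor``; mates inside a
    low-mappability artifact get MAPQ 10 instead of 60.
    """
    rng = _rng(config, 2)
    rl = config.read_length
    donor_len, bp, cum = _donor_map(truth.true_deletions, config.chrom_length)
    if donor_len <= 2 * rl:
        raise ValueError("chromosome too short after excision")

    n_frag = int(round(config.coverage * config.chrom_length / (2.0 * rl)))
    fl = np.rint(rng.normal(config.insert_mean, config.insert_sd, n_frag)).astype(np.int64)
    fl = np.maximum(fl, 2 * rl)
    starts = np.floor(rng.random(n_frag) * (donor_len - fl)).astype(np.int64)

    a1, a2 = starts, starts + fl - rl  # donor starts of the two mates
    # drop fragments whose mates cross an excision point
    def crosses(a):
        return np.searchsorted(bp, a + rl, side="left") > \
               np.searchsorted(bp, a, side="right")
    keep = ~(crosses(a1) | crosses(a2))

    k1 = np.searchsorted(bp, a1, side="right")
    k2 = np.searchsorted(bp, a2, side="right")
    r1 = a1 + cum[k1]
    r2 = a2 + cum[k2]

    # thin fragments overlapping bias artifacts; drop MAPQ inside
    # low-mappability artifacts
    mapq1 = np.full(n_frag, 60, dtype=np.int64)
    mapq2 = np.full(n_frag, 60, dtype=np.int64)
    thin = rng.random(n_frag)
    for rec in truth.bias_artifacts:
        s, e = rec.interval.start, rec.interval.end
        overlap = (r1 < e) & (r2 + rl > s)
        keep &= ~overlap | (thin < config.artifact_coverage_factor)
        if rec.cause == "low_mappability":
            m1_in = (r1 < e) & (r1 + rl > s)
            m2_in = (r2 < e) & (r2 + rl > s)
            mapq1[m1_in] = 10
            mapq2[m2_in] = 10

    idx = np.flatnonzero(keep)
    tlen = (r2 + rl - r1).astype(np.int64)
    proper = tlen <= config.insert_mean + 10 * config.insert_sd

    chrom = config.chrom_name
    tmp_sam = out_bam + ".tmp.sam"
    with open(tmp_sam, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{chrom}\tLN:{config.chrom_length}\n")
        lines = []
        for i in idx:
            f1, f2 = (99, 147) if proper[i] else (97, 145)
            p1, p2, t = r1[i] + 1, r2[i] + 1, tlen[i]
            q = f"sim{i:07d}"
            lines.append(
                f"{q}\t{f1}\t{chrom}\t{p1}\t{mapq1[i]}\t{rl}M\t=\t{p2}\t{t}\t*\t*\n"
                f"{q}\t{f2}\t{chrom}\t{p2}\t{mapq2[i]}\t{rl}M\t=\t{p1}\t{-t}\t*\t*\n"
            )
            if len(lines) >= 50_000:
                fh.write("".join(lines))
                lines.clear()
        fh.write("".join(lines))
    pysam.sort("-O", "bam", "-o", out_bam, tmp_sam)
    os.remove(tmp_sam)
    pysam.index(out_bam)
    return out_bam


_DECOY_KINDS = ("wrong_subtype", "oversize", "no_samples", "wrong_method", "size_10k")


def emit_variant_table(config: SimConfig, truth: SimTruth, path: str) -> None:
    """Write a DGV-style supporting-variants TSV for the planted features.

    One row per true deletion and per bias artifact (the artifact rows
    model coverage-valley miscalls), with subtype alternating between
    ``deletion`` and ``loss``; plus ``n_decoys`` rows that the filters
    must reject (wrong subtype, oversize, empty samples, wrong method, and
    size exactly 10 kbp).  Coordinates are written 1-based inclusive.
    """
    rng = _rng(config, 3)
    header = "variantaccession\tchr\tstart\tend\tvarianttype\tvariantsubtype\treference\tmethod\tsamples\n"
    rows = []
    for i, rec in enumerate(truth.records):
        subtype = "deletion" if i % 2 == 0 else "loss"
        rows.append(
            f"{rec.accession}\t{rec.interval.chrom}\t{rec.interval.start + 1}\t"
            f"{rec.interval.end}\tCNV\t{subtype}\t{config.study_name}\t"
            f"sequencing\t{config.sample_name}\n"
        )
    for j in range(config.n_decoys):
        kind = _DECOY_KINDS[j % len(_DECOY_KINDS)]
        start = int(rng.integers(1, max(2, config.chrom_length - 15_000)))
        subtype, method, samples, size = "deletion", "sequencing", config.sample_name, 2000
        if kind == "wrong_subtype":
            subtype = "duplication"
        elif kind == "oversize":
            size = 12_000
        elif kind == "no_samples":
            samples = ""
        elif kind == "wrong_method":
            method = "aCGH"
        elif kind == "size_10k":
            size = 10_000
        rows.append(
            f"essv{3000000 + j}\t{config.chrom_name}\t{start}\t{start + size - 1}\t"
            f"CNV\t{subtype}\t{config.study_name}\t{method}\t{samples}\n"
        )
    with open(path, "w") as fh:
        fh.write(header)
        fh.writelines(rows)


def write_truth_table(truth: SimTruth, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("accession\tkind\tcause\tchrom\tstart\tend\tsize\texpected_verdict\n")
        for r in truth.records:
            fh.write(
                f"{r.accession}\t{r.kind}\t{r.cause or ''}\t{r.interval.chrom}\t"
                f"{r.interval.start + 1}\t{r.interval.end}\t{r.interval.length}\t"
                f"{r.expected_verdict}\n"
            )


def read_truth_table(path: str) -> SimTruth:
    records = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            acc, kind, cause, chrom, start, end, _size, verdict = line.rstrip("\n").split("\t")
            records.append(
                TruthRecord(
                    acc,
                    GenomicInterval(chrom, int(start) - 1, int(end)),
                    kind,  # type: ignore[arg-type]
                    cause or None,  # type: ignore[arg-type]
                    verdict,  # type: ignore[arg-type]
                )
            )
    return SimTruth(records)


@dataclass
class SimOutputs:
    gc_bedgraph: str
    map_bedgraph: str
    bam: str
    variants_tsv: str
    truth_tsv: str
    manifest_tsv: str
    truth: SimTruth
    gc_track: BinnedTrack
    map_track: BinnedTrack


def simulate(config: SimConfig, out_dir: str) -> SimOutputs:
    """Run the full simulator and write every artifact into *out_dir*."""
    os.makedirs(out_dir, exist_ok=True)
    truth = plan_truth(config)
    gc_track, map_track, _ = simulate_profiles(config, truth)

    gc_path = os.path.join(out_dir, "gc.bedgraph")
    map_path = os.path.join(out_dir, "mappability.bedgraph")
    bam_path = os.path.join(out_dir, "reads.bam")
    variants_path = os.path.join(out_dir, "variants.tsv")
    truth_path = os.path.join(out_dir, "truth.tsv")
    manifest_path = os.path.join(out_dir, "manifest.tsv")

    write_bedgraph(gc_track, gc_path)
    write_bedgraph(map_track, map_path)
    simulate_read_pairs(config, truth, bam_path)
    emit_variant_table(config, truth, variants_path)
    write_truth_table(truth, truth_path)
    with open(manifest_path, "w") as fh:
        fh.write(f"{config.sample_name}\t{os.path.abspath(bam_path)}\n")

    return SimOutputs(
        gc_bedgraph=gc_path,
        map_bedgraph=map_path,
        bam=bam_path,
        variants_tsv=variants_path,
        truth_tsv=truth_path,
        manifest_tsv=manifest_path,
        truth=truth,
        gc_track=gc_track,
        map_track=map_track,
    )
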