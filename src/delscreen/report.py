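"""Result spreadsheets, per-variant diagnostic figures, summary statistics.

Summary statistics mirror the downstream analysis of the screen: tallies
of suspicious variants and false positives per chromosome / sample /
study, the Pearson correlation between chromosome length and
false-positive count, and a 3-component Gaussian mixture over
log10(variant size) capturing the size modalities.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .intervals import GenomicInterval
from .pem import ValidationResult, write_results_tsv
from .profiles import BinnedTrack

__all__ = [
    "SummaryStats",
    "MixtureFit",
    "write_results_spreadsheet",
    "summarize",
    "fit_log_size_mixture",
    "plot_variant",
    "write_summary",
]

logger = logging.getLogger(__name__)


@dataclass
class MixtureFit:
    """A 1-D Gaussian mixture over log10(size), fitted by EM."""

    means: np.ndarray  # log10 scale, ascending
    sds: np.ndarray
    weights: np.ndarray
    log_likelihoods: list[float]  # per-iteration trajectory (non-decreasing)

    @property
    def means_bp(self) -> np.ndarray:
        """Component means expressed in base pairs (10**mean)."""
        return 10.0 ** self.means


@dataclass
class SummaryStats:
    per_chromosome: dict[str, dict[str, int]]
    per_sample: dict[str, dict[str, int]]
    per_study: dict[str, dict[str, int]]
    n_suspicious: int
    n_false_positive: int
    n_true_positive: int
    n_unresolvable: int
    size_log10_false_positives: list[float]
    chromosome_length_correlation: tuple[float, float] | None
    size_modality_fit: MixtureFit | None


def write_results_spreadsheet(results: Sequence[ValidationResult], path) -> None:
    """One row per suspicious variant, deterministic order (chrom, start, accession)."""
    write_results_tsv(results, path)


def _kmeans_1d(x: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """Tiny deterministic Lloyd's algorithm; centres seeded at spread quantiles."""
    centres = np.quantile(x, (np.arange(k) + 0.5) / k)
    for _ in range(max_iter):
        assign = np.argmin(np.abs(x[:, None] - centres[None, :]), axis=1)
        new = np.array([
            x[assign == j].mean() if np.any(assign == j) else centres[j]
            for j in range(k)
        ])
        if np.allclose(new, centres):
            break
        centres = new
    return np.sort(centres)


def fit_log_size_mixture(
    sizes_bp: Sequence[float],
    n_components: int = 3,
    max_iter: int = 500,
    tol: float = 1e-9,
) -> MixtureFit:
    """Fit a Gaussian mixture to log10(size) by EM with k-means initialization.

    Fully deterministic: initial means come from 1-D k-means, initial
    weights are uniform, and initial variances are the within-cluster
    variances (floored).  The per-iteration log-likelihood trajectory is
    recorded and is non-decreasing up to floating-point tolerance.
    """
    x = np.log10(np.asarray(sizes_bp, dtype=float))
    if len(np.unique(x)) < n_components:
        raise ValueError(
            f"need at least {n_components} distinct sizes to fit the mixture"
        )
    k = n_components
    means = _kmeans_1d(x, k)
    assign = np.argmin(np.abs(x[:, None] - means[None, :]), axis=1)
    var_floor = max(x.var() * 1e-4, 1e-6)
    sds = np.array([
        max(x[assign == j].std(), math.sqrt(var_floor)) if np.any(assign == j)
        else x.std() or 1.0
        for j in range(k)
    ])
    weights = np.full(k, 1.0 / k)

    trajectory: list[float] = []
    for _ in range(max_iter):
        # E-step
        comp = weights[None, :] * stats.norm.pdf(x[:, None], means[None, :], sds[None, :])
        total = comp.sum(axis=1)
        total = np.maximum(total, 1e-300)
        ll = float(np.log(total).sum())
        resp = comp / total[:, None]
        # M-step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        weights = nk / len(x)
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.sqrt(np.maximum(var, var_floor))
        if trajectory and abs(ll - trajectory[-1]) < tol * max(1.0, abs(ll)):
            trajectory.append(ll)
            break
        trajectory.append(ll)

    order = np.argsort(means)
    return MixtureFit(
        means=means[order], sds=sds[order], weights=weights[order],
        log_likelihoods=trajectory,
    )


def _tally(results, key) -> dict[str, dict[str, int]]:
    out: dict[str, dict[str, int]] = {}
    for r in results:
        if r.verdict == "unresolvable":
            continue
        k = key(r) or "(none)"
        slot = out.setdefault(k, {"suspicious": 0, "false_positive": 0})
        slot["suspicious"] += 1
        if r.verdict == "false_positive":
            slot["false_positive"] += 1
    return out


def summarize(
    results: Sequence[ValidationResult],
    chrom_lengths: dict[str, int] | None = None,
    n_components: int = 3,
) -> SummaryStats:
    """Aggregate validation results into the summary statistics.

    The chromosome-length correlation is Pearson's r (with its t-test
    p-value) between chromosome length and false-positive count, over the
    chromosomes present in *chrom_lengths*; it is None when fewer than two
    chromosomes contribute.  The size-modality fit is skipped (None) with
    a warning when there are fewer than ``n_components`` distinct
    false-positive sizes.
    """
    validated = [r for r in results if r.verdict != "unresolvable"]
    n_unres = len(results) - len(validated)
    fps = [r for r in validated if r.verdict == "false_positive"]

    per_chrom = _tally(validated, lambda r: r.chrom)
    per_sample = _tally(validated, lambda r: r.sample)
    per_study = _tally(validated, lambda r: r.reference)

    corr = None
    if chrom_lengths and len(chrom_lengths) >= 2:
        chroms = sorted(chrom_lengths)
        lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
        counts = np.array(
            [per_chrom.get(c, {}).get("false_positive", 0) for c in chroms],
            dtype=float,
        )
        if np.ptp(lengths) > 0 and np.ptp(counts) > 0:
            r, p = stats.pearsonr(lengths, counts)
            corr = (float(r), float(p))
        elif np.ptp(lengths) > 0 and len(set(counts)) == 1:
            logger.warning("constant false-positive counts; correlation undefined")

    sizes = [float(r.end - r.start) for r in fps]
    fit = None
    if len(set(sizes)) >= n_components:
        fit = fit_log_size_mixture(sizes, n_components=n_components)
    elif sizes:
        logger.warning(
            "only %d distinct false-positive sizes; mixture fit skipped", len(set(sizes))
        )

    return SummaryStats(
        per_chromosome=per_chrom,
        per_sample=per_sample,
        per_study=per_study,
        n_suspicious=len(validated),
        n_false_positive=len(fps),
        n_true_positive=sum(r.verdict == "true_positive" for r in validated),
        n_unresolvable=n_unres,
        size_log10_false_positives=[math.log10(s) for s in sizes],
        chromosome_length_correlation=corr,
        size_modality_fit=fit,
    )


def write_summary(summary: SummaryStats, tsv_path, json_path=None) -> None:
    """Write the tallies as TSV and (optionally) the full summary as JSON."""
    with open(tsv_path, "w") as fh:
        fh.write("group\tkey\tsuspicious\tfalse_positive\n")
        for group, table in (
            ("chromosome", summary.per_chromosome),
            ("sample", summary.per_sample),
            ("study", summary.per_study),
        ):
            for key in sorted(table):
                row = table[key]
                fh.write(f"{group}\t{key}\t{row['suspicious']}\t{row['false_positive']}\n")
    if json_path is None:
        return
    payload = {
        "n_suspicious": summary.n_suspicious,
        "n_false_positive": summary.n_false_positive,
        "n_true_positive": summary.n_true_positive,
        "n_unresolvable": summary.n_unresolvable,
        "per_chromosome": summary.per_chromosome,
        "per_sample": summary.per_sample,
        "per_study": summary.per_study,
        "chromosome_length_correlation": summary.chromosome_length_correlation,
        "size_modality_fit": None
        if summary.size_modality_fit is None
        else {
            "means_log10": summary.size_modality_fit.means.tolist(),
            "means_bp": summary.size_modality_fit.means_bp.tolist(),
            "sds_log10": summary.size_modality_fit.sds.tolist(),
            "weights": summary.size_modality_fit.weights.tolist(),
        },
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2)


def plot_variant(
    variant: GenomicInterval,
    gc_track: BinnedTrack | None,
    map_track: BinnedTrack | None,
    doc_profile: BinnedTrack | None,
    pairs,
    out_path,
    title: str = "",
) -> str:
    """Render the four-panel diagnostic figure for one variant.

    Left column: GC content, mappability and depth of coverage over the
    ROI, with the variant drawn as a bar in each panel.  Right panel: one
    horizontal line per read pair at distinct vertical offsets, coloured
    by pair quality (empty when there are no pairs).
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(10, 6))
    gs = fig.add_gridspec(3, 2, width_ratios=[1.0, 1.2])
    panels = [
        ("GC content", gc_track, "m"),
        ("mappability", map_track, "r"),
        ("DOC", doc_profile, "b"),
    ]
    for row, (label, track, colour) in enumerate(panels):
        ax = fig.add_subplot(gs[row, 0])
        if track is not None:
            xs = track.origin + np.arange(track.n_bins) * track.bin_size
            ax.plot(xs, track.values, color=colour, lw=0.8)
        ax.axvspan(variant.start, variant.end, color="green", alpha=0.3)
        ax.set_ylabel(label, fontsize=8)
        if row < 2:
            ax.set_xticklabels([])

    ax = fig.add_subplot(gs[:, 1])
    if pairs:
        qualities = [p.pair_quality for p in pairs]
        vmax = max(max(qualities), 1.0)
        cmap = plt.get_cmap("cividis_r")
        for y, p in enumerate(sorted(pairs, key=lambda p: p.outer_span.start)):
            span = p.outer_span
            ax.hlines(y, span.start, span.end,
                      color=cmap(p.pair_quality / vmax), lw=1.5)
        ax.set_ylim(-1, len(pairs))
    ax.axvspan(variant.start, variant.end, color="green", alpha=0.3)
    ax.set_ylabel("read pairs", fontsize=8)
    ax.set_xlabel(variant.chrom)
    if title:
        fig.suptitle(title, fontsize=10)
    fig.tight_layout()
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
    return str(out_path)
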