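"""DGV-style supporting-variant tables: parsing, filtering, dedup, flagging.

Supporting-variant tables are tab-separated with 1-based inclusive
coordinates; they are converted to the internal 0-based half-open
convention on read.  Filtering keeps sequencing-method deletion/loss
records strictly smaller than 10 kbp with a nonempty sample field;
duplicates (same chromosome and location) are merged; variants whose span
falls within a suspicious region at F-score > 0.9 are flagged for
paired-end validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

from .intervals import GenomicInterval, max_fscore_against_set
from .profiles import SuspiciousRegion

__all__ = [
    "SupportingVariant",
    "FilterConfig",
    "read_dgv_table",
    "filter_variants",
    "merge_duplicates",
    "flag_suspicious",
    "write_flagged_tsv",
    "read_flagged_tsv",
    "read_manifest",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "variantaccession",
    "chr",
    "start",
    "end",
    "varianttype",
    "variantsubtype",
    "reference",
    "method",
    "samples",
)


@dataclass
class SupportingVariant:
    """One sample-level variant record from a DGV-style table."""

    accession: str
    interval: GenomicInterval
    variant_type: str
    variant_subtype: str
    method: str
    reference: str
    samples: list[str]
    merged_accessions: list[str] = field(default_factory=list)
    # annotations attached by flag_suspicious
    fscore: float | None = None
    cause: str | None = None

    def __post_init__(self) -> None:
        if not self.merged_accessions:
            self.merged_accessions = [self.accession]

    @property
    def size(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class FilterConfig:
    """The variant filter: sequencing-method deletion/loss, < 10 kbp, sampled."""

    required_method_token: str = "sequencing"
    allowed_subtypes: frozenset[str] = frozenset({"deletion", "loss"})
    max_size: int = 10_000
    require_samples: bool = True

    def __post_init__(self) -> None:
        if self.max_size <= 0:
            raise ValueError("max_size must be positive")


def normalize_chrom(chrom: str) -> str:
    chrom = str(chrom).strip()
    return chrom if chrom.lower().startswith("chr") else f"chr{chrom}"


def _split_samples(raw) -> list[str]:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return []
    return [tok.strip() for tok in str(raw).replace('"', "").split(",") if tok.strip()]


def read_dgv_table(path) -> list[SupportingVariant]:
    """Parse a DGV-style supporting-variants TSV.

    Coordinates are 1-based inclusive in the file and converted to 0-based
    half-open.  Rows with non-numeric or inverted coordinates are skipped
    with a logged warning.  A missing required column raises.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")

    variants: list[SupportingVariant] = []
    n_skipped = 0
    for row in df.itertuples(index=False):
        rec = row._asdict()
        try:
            start = int(rec["start"])
            end = int(rec["end"])
        except (TypeError, ValueError):
            n_skipped += 1
            logger.warning(
                "skipping %s: non-numeric coordinates (%r, %r)",
                rec["variantaccession"], rec["start"], rec["end"],
            )
            continue
        if end < start or start < 1:
            n_skipped += 1
            logger.warning(
                "skipping %s: inverted or out-of-range coordinates %d-%d",
                rec["variantaccession"], start, end,
            )
            continue
        variants.append(
            SupportingVariant(
                accession=rec["variantaccession"].strip(),
                interval=GenomicInterval(normalize_chrom(rec["chr"]), start - 1, end),
                variant_type=rec["varianttype"].strip(),
                variant_subtype=rec["variantsubtype"].strip(),
                method=rec["method"].strip(),
                reference=rec["reference"].strip(),
                samples=_split_samples(rec["samples"]),
            )
        )
    if n_skipped:
        logger.warning("%s: skipped %d malformed row(s)", path, n_skipped)
    return variants


def filter_variants(
    variants: list[SupportingVariant], config: FilterConfig = FilterConfig()
) -> list[SupportingVariant]:
    """Apply the four-part variant filter, preserving input order.

    Keeps records whose method contains the required token
    (case-insensitive), whose subtype is an allowed one, whose size is
    strictly below ``max_size``, and whose sample list is nonempty (when
    required).  Per-criterion rejection tallies are logged.
    """
    token = config.required_method_token.lower()
    allowed = {s.lower() for s in config.allowed_subtypes}
    rejected = {"method": 0, "subtype": 0, "size": 0, "samples": 0}
    kept: list[SupportingVariant] = []
    for v in variants:
        if token not in v.method.lower():
            rejected["method"] += 1
        elif v.variant_subtype.lower() not in allowed:
            rejected["subtype"] += 1
        elif v.size >= config.max_size:
            rejected["size"] += 1
        elif config.require_samples and not v.samples:
            rejected["samples"] += 1
        else:
            kept.append(v)
    logger.info(
        "filter_variants: kept %d of %d (rejected: %s)",
        len(kept), len(variants),
        ", ".join(f"{k}={n}" for k, n in rejected.items()),
    )
    return kept


def merge_duplicates(variants: list[SupportingVariant]) -> list[SupportingVariant]:
    """Merge records sharing an identical (chrom, start, end) locus.

    The merged record keeps the lexicographically smallest accession, the
    union of samples, the union of study labels (joined with ';'), and
    every constituent accession in ``merged_accessions``.  Output is
    ordered by first appearance of each locus.
    """
    by_locus: dict[tuple[str, int, int], list[SupportingVariant]] = {}
    order: list[tuple[str, int, int]] = []
    for v in variants:
        key = (v.interval.chrom, v.interval.start, v.interval.end)
        if key not in by_locus:
            by_locus[key] = []
            order.append(key)
        by_locus[key].append(v)

    merged: list[SupportingVariant] = []
    for key in order:
        group = sorted(by_locus[key], key=lambda v: v.accession)
        head = group[0]
        if len(group) == 1:
            merged.append(head)
            continue
        samples = sorted({s for v in group for s in v.samples})
        references = sorted({v.reference for v in group if v.reference})
        accessions = sorted({a for v in group for a in v.merged_accessions})
        merged.append(
            replace(
                head,
                samples=samples,
                reference=";".join(references),
                merged_accessions=accessions,
            )
        )
    return merged


def flag_suspicious(
    variants: list[SupportingVariant],
    suspicious_regions: list[GenomicInterval],
    f_threshold: float = 0.9,
    causes: list[SuspiciousRegion] | None = None,
) -> list[SupportingVariant]:
    """Flag variants whose best F-score against the suspicious regions exceeds
    ``f_threshold`` (strictly).

    Each flagged variant is annotated with the achieved F-score and, when
    *causes* (the pre-merge cause-labelled regions) is given, with the
    cause(s) of the overlapping region(s).
    """
    flagged: list[SupportingVariant] = []
    for v in variants:
        score = max_fscore_against_set(v.interval, suspicious_regions)
        if score.fscore > f_threshold:
            cause = None
            if causes:
                hits = sorted(
                    {c.cause for c in causes if c.interval.intersection_length(v.interval) > 0}
                )
                cause = "+".join(hits) if hits else None
            flagged.append(replace(v, fscore=score.fscore, cause=cause))
    return flagged


_FLAGGED_COLUMNS = [
    "accession", "chrom", "start", "end", "size",
    "subtype", "reference", "samples", "fscore", "cause",
]


def write_flagged_tsv(variants: list[SupportingVariant], path) -> None:
    """Write flagged variants as TSV (coordinates 1-based inclusive, as DGV)."""
    rows = [
        {
            "accession": v.accession,
            "chrom": v.interval.chrom,
            "start": v.interval.start + 1,
            "end": v.interval.end,
            "size": v.size,
            "subtype": v.variant_subtype,
            "reference": v.reference,
            "samples": ",".join(v.samples),
            "fscore": "" if v.fscore is None else f"{v.fscore:.4f}",
            "cause": v.cause or "",
        }
        for v in variants
    ]
    pd.DataFrame(rows, columns=_FLAGGED_COLUMNS).to_csv(path, sep="\t", index=False)


def read_flagged_tsv(path) -> list[SupportingVariant]:
    """Read a flagged-variant TSV back into records."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: list[SupportingVariant] = []
    for row in df.itertuples(index=False):
        rec = row._asdict()
        out.append(
            SupportingVariant(
                accession=rec["accession"],
                interval=GenomicInterval(
                    rec["chrom"], int(rec["start"]) - 1, int(rec["end"])
                ),
                variant_type="CNV",
                variant_subtype=rec.get("subtype", ""),
                method="sequencing",
                reference=rec.get("reference", ""),
                samples=_split_samples(rec.get("samples", "")),
                fscore=float(rec["fscore"]) if rec.get("fscore") else None,
                cause=rec.get("cause") or None,
            )
        )
    return out


def read_manifest(path) -> dict[str, str]:
    """Read a two-column (sample-id, alignment-path) manifest TSV."""
    manifest: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"manifest line needs 2 columns: {line!r}")
            if parts[0].lower() in {"sample", "sample_id"}:
                continue
            manifest[parts[0]] = parts[1]
    return manifest
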