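"""Breakpoint feature extraction for the false-positive decision model.

Three feature families are computed per SV candidate:

1. read statistics in a window (default ±20 bp) around each breakpoint —
   depth, soft-clip counts and clip-length min/max/mean, mapping-quality
   min/max/mean, mean base quality, discordant-pair count;
2. simple-repeat overlap flags for each breakpoint;
3. caller support counts — DV (discordant variant pairs), RV (variant
   junction reads), their sum, and the junction-read fraction RV/(DV+RV).

The schema is fixed and versioned; a hash of it travels with every trained
model so that a bundle refuses feature matrices built under a different
schema.
"""

from __future__ import annotations

import bisect
import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .types import AlignedReadView, Breakpoint, RepeatTrack, SVRecord

SCHEMA_VERSION = "1"

_PER_BP = [
    "depth",
    "clip_count",
    "clip_len_min",
    "clip_len_max",
    "clip_len_mean",
    "mapq_min",
    "mapq_max",
    "mapq_mean",
    "basequal_mean",
    "discordant_count",
    "repeat",
    "no_reads",
]
_SHARED = [
    "dv",
    "rv",
    "dv_rv_sum",
    "rv_fraction",
    "rv_fraction_imputed",
    "support_missing",
    "svtype_DEL",
    "svtype_DUP",
    "svtype_INS",
    "svtype_INV",
    "svtype_BND",
    "interchrom",
]

#: Fixed, ordered feature schema (version 1).
SCHEMA: List[str] = [f"bp{i}_{name}" for i in (1, 2) for name in _PER_BP] + _SHARED


def schema_hash(columns: Sequence[str] = SCHEMA, version: str = SCHEMA_VERSION) -> str:
    payload = f"v{version}:" + ",".join(columns)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class FeatureConfig:
    """Extraction parameters.

    window_bp
        Half-width of the breakpoint window in bp; reads with any aligned
        base in ``[pos - window_bp, pos + window_bp)`` are in the window.
    discordant_mate_bp
        A non-proper pair in the window counts as discordant support when its
        mate maps within this distance of the partner breakpoint.
    """

    window_bp: int = 20
    discordant_mate_bp: int = 1000
    schema_version: str = SCHEMA_VERSION
    schema: List[str] = field(default_factory=lambda: list(SCHEMA))

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if len(set(self.schema)) != len(self.schema):
            raise ValueError("schema contains duplicate feature names")

    @property
    def hash(self) -> str:
        return schema_hash(self.schema, self.schema_version)


@dataclass
class FeatureMatrix:
    """Rectangular feature table: one row per SV candidate, schema-ordered columns."""

    data: pd.DataFrame
    schema_hash: str

    @property
    def ids(self) -> List[str]:
        return list(self.data.index)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)


class AlignmentIndex:
    """Position-indexed store of aligned reads for fast window queries."""

    def __init__(self, reads: Iterable[AlignedReadView]):
        by_chrom: Dict[str, List[AlignedReadView]] = {}
        for r in reads:
            by_chrom.setdefault(r.chrom, []).append(r)
        self._reads: Dict[str, List[AlignedReadView]] = {}
        self._starts: Dict[str, List[int]] = {}
        self._max_span: Dict[str, int] = {}
        for chrom, rs in by_chrom.items():
            rs.sort(key=lambda r: r.pos)
            self._reads[chrom] = rs
            self._starts[chrom] = [r.pos for r in rs]
            self._max_span[chrom] = max(r.reference_length for r in rs)

    @classmethod
    def from_sam(cls, path: str) -> "AlignmentIndex":
        from .io import read_sam

        return cls(read_sam(path))

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self._reads

    def fetch(self, chrom: str, start: int, end: int) -> List[AlignedReadView]:
        """Reads with >=1 aligned base in ``[start, end)``."""
        rs = self._reads.get(chrom)
        if not rs:
            return []
        starts = self._starts[chrom]
        lo = bisect.bisect_left(starts, start - self._max_span[chrom])
        hi = bisect.bisect_left(starts, end)
        return [r for r in rs[lo:hi] if r.reference_end > start]


def _stats(values: Sequence[float]) -> tuple:
    if not values:
        return 0.0, 0.0, 0.0
    arr = np.asarray(values, dtype=float)
    return float(arr.min()), float(arr.max()), float(arr.mean())


def window_stats(
    reads: Sequence[AlignedReadView],
    bp: Breakpoint,
    cfg: FeatureConfig,
    partner: Optional[Breakpoint] = None,
) -> Dict[str, float]:
    """Per-breakpoint read statistics over the ±window_bp window.

    Soft-clip statistics are computed over clips whose boundary (the
    reference coordinate where clipped bases begin) falls inside the window.
    Empty windows yield zero counts, zero-imputed statistics, and
    ``no_reads = 1``.
    """
    w = cfg.window_bp
    start, end = bp.pos - w, bp.pos + w
    in_window = [r for r in reads if r.overlaps(bp.chrom, start, end)]

    clip_lengths: List[int] = []
    clipped_reads = 0
    for r in in_window:
        lengths = []
        if r.soft_clip_left > 0 and start <= r.pos < end:
            lengths.append(r.soft_clip_left)
        if r.soft_clip_right > 0 and start <= r.reference_end < end:
            lengths.append(r.soft_clip_right)
        if lengths:
            clipped_reads += 1
            clip_lengths.extend(lengths)

    discordant = 0
    for r in in_window:
        if r.is_proper_pair or r.mate_chrom is None:
            continue
        if partner is None:
            discordant += 1
        elif r.mate_chrom == partner.chrom and abs(
            (r.mate_pos or 0) - partner.pos
        ) <= cfg.discordant_mate_bp:
            discordant += 1

    clip_min, clip_max, clip_mean = _stats(clip_lengths)
    mapq_min, mapq_max, mapq_mean = _stats([r.mapq for r in in_window])
    bq_means = [float(np.mean(r.base_qualities)) for r in in_window if len(r.base_qualities)]
    return {
        "depth": float(len(in_window)),
        "clip_count": float(clipped_reads),
        "clip_len_min": clip_min,
        "clip_len_max": clip_max,
        "clip_len_mean": clip_mean,
        "mapq_min": mapq_min,
        "mapq_max": mapq_max,
        "mapq_mean": mapq_mean,
        "basequal_mean": float(np.mean(bq_means)) if bq_means else 0.0,
        "discordant_count": float(discordant),
        "no_reads": 0.0 if in_window else 1.0,
    }


def repeat_flags(rec: SVRecord, track: RepeatTrack) -> tuple:
    """(flag1, flag2): 1 iff the breakpoint lies inside a simple-repeat interval."""
    return (
        1 if track.query(rec.bp1.chrom, rec.bp1.pos) else 0,
        1 if track.query(rec.bp2.chrom, rec.bp2.pos) else 0,
    )


def support_features(rec: SVRecord) -> Dict[str, float]:
    """Caller support block: DV, RV, DV+RV, and the junction-read fraction.

    Missing counts are imputed to 0 with ``support_missing = 1``; an
    undefined fraction (DV+RV = 0) is imputed to 0 with
    ``rv_fraction_imputed = 1``.
    """
    dv_raw, rv_raw = rec.support.DV, rec.support.RV
    missing = dv_raw is None or rv_raw is None
    dv = float(dv_raw or 0)
    rv = float(rv_raw or 0)
    total = dv + rv
    return {
        "dv": dv,
        "rv": rv,
        "dv_rv_sum": total,
        "rv_fraction": rv / total if total > 0 else 0.0,
        "rv_fraction_imputed": 0.0 if total > 0 else 1.0,
        "support_missing": 1.0 if missing else 0.0,
    }


AlignmentsLike = Union[AlignmentIndex, Sequence[AlignedReadView], str]


def _as_index(alignments: AlignmentsLike) -> AlignmentIndex:
    if isinstance(alignments, AlignmentIndex):
        return alignments
    if isinstance(alignments, str):
        return AlignmentIndex.from_sam(alignments)
    return AlignmentIndex(alignments)


def build_feature_matrix(
    records: Sequence[SVRecord],
    alignments: AlignmentsLike,
    track: Optional[RepeatTrack] = None,
    cfg: Optional[FeatureConfig] = None,
) -> FeatureMatrix:
    """One schema-ordered feature row per SV candidate.

    Deterministic given inputs; a record whose breakpoint falls outside the
    territory covered by the alignments gets empty-window semantics and a
    warning.
    """
    cfg = cfg or FeatureConfig()
    track = track or RepeatTrack()
    index = _as_index(alignments)
    rows = []
    ids = []
    for rec in records:
        row: Dict[str, float] = {}
        flags = repeat_flags(rec, track)
        for i, (bp, partner) in enumerate(((rec.bp1, rec.bp2), (rec.bp2, rec.bp1)), start=1):
            if not index.has_chrom(bp.chrom):
                warnings.warn(
                    f"record {rec.id}: breakpoint {bp.chrom}:{bp.pos} outside "
                    "alignment territory; empty-window features"
                )
                reads: List[AlignedReadView] = []
            else:
                reads = index.fetch(bp.chrom, bp.pos - cfg.window_bp, bp.pos + cfg.window_bp)
            block = window_stats(reads, bp, cfg, partner=partner)
            block["repeat"] = float(flags[i - 1])
            for name, value in block.items():
                row[f"bp{i}_{name}"] = value
        row.update(support_features(rec))
        for svtype in ("DEL", "DUP", "INS", "INV", "BND"):
            row[f"svtype_{svtype}"] = 1.0 if rec.svtype == svtype else 0.0
        row["interchrom"] = 1.0 if rec.interchromosomal else 0.0
        rows.append([row[name] for name in cfg.schema])
        ids.append(rec.id)
    if len(set(ids)) != len(ids):
        raise ValueError("record ids are not unique")
    df = pd.DataFrame(rows, index=pd.Index(ids, name="id"), columns=cfg.schema, dtype=float)
    if len(df) and not np.isfinite(df.to_numpy()).all():
        raise AssertionError("non-finite feature values after imputation")
    return FeatureMatrix(data=df, schema_hash=cfg.hash)
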