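"""Desk-scale spike-in simulator: SV-free background alignments plus
evidence planting at controlled VAF, with matched truth sets.

The generator works at the alignment level rather than editing reads and
re-aligning them: a read pair crossing a breakpoint is converted, with
probability equal to the target variant allele fraction, into SV-supporting
evidence — a split read whose soft-clip boundary sits at the breakpoint
(with small configurable jitter) and a discordant pair joining the two
breakpoints.  This matches the allele-sampling semantics of read-editing
spike-in tools while producing exactly what the downstream feature extractor
consumes.

Also provides ``synth_feature_table``, a generator of labeled feature tables
in the extractor's schema with a controllable class separation, used to
exercise the decision model.
"""

from __future__ import annotations

import csv
import warnings
import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .features import SCHEMA, FeatureMatrix, schema_hash
from .types import (
    AlignedReadView,
    Breakpoint,
    GenomicInterval,
    SupportCounts,
    SVRecord,
)

#: The five VAF gradients used for caller benchmarking.
DEFAULT_GRADIENTS = (0.005, 0.01, 0.02, 0.05, 0.10)

TRUTH_COLUMNS = ["id", "svtype", "chrom1", "pos1", "chrom2", "pos2", "vaf", "support"]


@dataclass
class SpikeConfig:
    """Spike-in parameters.

    Defaults mirror standard panel spike-in settings: 100 bp reads, a
    100x minimum locus depth, and at least 3 planted supporting reads per
    event.
    """

    vaf: float = 0.0
    read_length: int = 100
    min_depth: int = 100
    min_mut_reads: int = 3
    seed: int = 0
    insert_size_mean: float = 300.0
    insert_size_sd: float = 40.0
    clip_jitter_bp: int = 2
    base_quality_mean: float = 34.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError("vaf must be in [0, 1]")
        if self.min_mut_reads < 0:
            raise ValueError("min_mut_reads must be >= 0")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")


@dataclass
class TruthSV:
    """A planted SV with its target VAF and realized supporting-read count."""

    record: SVRecord
    vaf: float
    support: int
    crossing_pairs: int = 0
    forced_topup: bool = False

    @property
    def id(self) -> str:
        return self.record.id

    @property
    def planted_fraction(self) -> Optional[float]:
        if self.crossing_pairs == 0:
            return None
        return self.support / self.crossing_pairs

    def as_call(self, caller: str = "sim") -> SVRecord:
        """The planted event as a caller-style record with DV/RV filled in."""
        return replace(
            self.record,
            caller=caller,
            support=SupportCounts(DV=self.support, RV=self.support),
        )


@dataclass
class SyntheticDataset:
    """Alignments plus truth for one simulated replicate."""

    alignments: List[AlignedReadView]
    truth: List[TruthSV] = field(default_factory=list)
    regions: List[GenomicInterval] = field(default_factory=list)
    replicate_id: int = 0
    vaf_gradient: Optional[float] = None

    def contig_lengths(self) -> Dict[str, int]:
        lengths: Dict[str, int] = {}
        for r in self.regions:
            lengths[r.chrom] = max(lengths.get(r.chrom, 0), r.end + 1000)
        for a in self.alignments:
            lengths[a.chrom] = max(lengths.get(a.chrom, 0), a.reference_end + 1000)
        return lengths


def generate_background(
    region: GenomicInterval, depth: float, cfg: SpikeConfig
) -> SyntheticDataset:
    """Concordant proper-pair background at a target mean depth, no SVs.

    Fragments are placed uniformly inside the region, so the mean per-base
    depth over the region equals the target by construction (within
    rounding).  Raises if the requested depth is below ``cfg.min_depth``.
    """
    if depth < cfg.min_depth:
        raise ValueError(f"depth {depth} below configured floor min_depth={cfg.min_depth}")
    rl = cfg.read_length
    if len(region) < 2 * rl:
        raise ValueError("region shorter than two read lengths")
    rng = np.random.default_rng(cfg.seed)
    n_pairs = int(round(depth * len(region) / (2 * rl)))
    inserts = np.maximum(
        2 * rl, rng.normal(cfg.insert_size_mean, cfg.insert_size_sd, n_pairs)
    ).astype(int)
    inserts = np.minimum(inserts, len(region))
    starts = region.start + (
        rng.random(n_pairs) * (len(region) - inserts)
    ).astype(int)
    mapqs = rng.choice([60, 60, 60, 60, 55, 40], size=n_pairs)
    quals = np.clip(
        rng.normal(cfg.base_quality_mean, 3, (2 * n_pairs, rl)).astype(int), 2, 40
    ).tolist()
    reads: List[AlignedReadView] = []
    for i in range(n_pairs):
        s, ins, mq = int(starts[i]), int(inserts[i]), int(mapqs[i])
        mate_start = s + ins - rl
        reads.append(
            AlignedReadView(
                name=f"bg{i}", chrom=region.chrom, pos=s, mapq=mq,
                cigar=[("M", rl)], is_proper_pair=True, is_reverse=False,
                mate_chrom=region.chrom, mate_pos=mate_start,
                base_qualities=quals[2 * i],
            )
        )
        reads.append(
            AlignedReadView(
                name=f"bg{i}", chrom=region.chrom, pos=mate_start, mapq=mq,
                cigar=[("M", rl)], is_proper_pair=True, is_reverse=True,
                mate_chrom=region.chrom, mate_pos=s,
                base_qualities=quals[2 * i + 1],
            )
        )
    return SyntheticDataset(alignments=reads, regions=[region])


def _crossing_pairs(
    reads: Sequence[AlignedReadView], bp: Breakpoint
) -> Dict[str, List[int]]:
    """Pair name -> indices of reads in that pair whose span contains bp.pos."""
    out: Dict[str, List[int]] = {}
    for i, r in enumerate(reads):
        if r.chrom == bp.chrom and r.pos <= bp.pos < r.reference_end:
            out.setdefault(r.name, []).append(i)
    return out


def _make_split(r: AlignedReadView, clip_pos: int) -> AlignedReadView:
    """Re-cigar a full-match read so a soft clip begins at ``clip_pos``."""
    qlen = sum(n for op, n in r.cigar if op in "MIS=X")
    left = clip_pos - r.pos
    right = r.reference_end - clip_pos
    if left >= right:  # clip the right side: [M left][S rest]
        m = max(1, min(left, qlen - 1))
        return replace(r, cigar=[("M", m), ("S", qlen - m)])
    # clip the left side: alignment restarts at clip_pos
    s = max(1, min(qlen - 1, qlen - right))
    return replace(r, pos=clip_pos, cigar=[("S", s), ("M", qlen - s)])


def spike_sv(ds: SyntheticDataset, sv: SVRecord, cfg: SpikeConfig) -> SyntheticDataset:
    """Plant supporting evidence for one SV at ``cfg.vaf`` into the dataset.

    Each read pair crossing a breakpoint is independently converted with
    probability ``vaf``: the crossing read becomes a split read soft-clipped
    at the breakpoint (±``clip_jitter_bp``) and the pair becomes discordant,
    its mate repositioned next to the partner breakpoint.  If fewer than
    ``min_mut_reads`` pairs convert, additional crossing pairs are converted
    and the truth record is flagged ``forced_topup``.
    """
    rng = np.random.default_rng(
        [cfg.seed, len(ds.truth), zlib.crc32(sv.id.encode()) & 0x7FFFFFFF]
    )
    reads = list(ds.alignments)
    if cfg.vaf == 0.0:
        truth = ds.truth + [TruthSV(record=sv, vaf=0.0, support=0)]
        return replace(ds, alignments=reads, truth=truth)

    converted_names: set = set()
    total_crossing = 0
    spare: List[Tuple[Breakpoint, Breakpoint, str, List[int]]] = []
    n_converted = 0
    for bp, partner in ((sv.bp1, sv.bp2), (sv.bp2, sv.bp1)):
        pairs = {
            name: idxs
            for name, idxs in _crossing_pairs(reads, bp).items()
            if name not in converted_names
        }
        if not pairs:
            raise ValueError(
                f"insufficient coverage: no read pairs cross {bp.chrom}:{bp.pos}"
            )
        total_crossing += len(pairs)
        take = rng.random(len(pairs)) < cfg.vaf
        for (name, idxs), hit in zip(sorted(pairs.items()), take):
            if hit:
                _convert_pair(reads, idxs, bp, partner, cfg, rng)
                converted_names.add(name)
                n_converted += 1
            else:
                spare.append((bp, partner, name, idxs))
    forced = False
    while n_converted < cfg.min_mut_reads and spare:
        bp, partner, name, idxs = spare.pop(0)
        if name in converted_names:
            continue
        _convert_pair(reads, idxs, bp, partner, cfg, rng)
        converted_names.add(name)
        n_converted += 1
        forced = True
    truth = ds.truth + [
        TruthSV(
            record=sv,
            vaf=cfg.vaf,
            support=n_converted,
            crossing_pairs=total_crossing,
            forced_topup=forced,
        )
    ]
    return replace(ds, alignments=reads, truth=truth)


def _convert_pair(
    reads: List[AlignedReadView],
    idxs: List[int],
    bp: Breakpoint,
    partner: Breakpoint,
    cfg: SpikeConfig,
    rng: np.random.Generator,
) -> None:
    jitter = int(rng.integers(0, cfg.clip_jitter_bp + 1)) * int(rng.choice([-1, 1]))
    split_i = idxs[0]
    r = reads[split_i]
    clip_pos = int(np.clip(bp.pos + jitter, r.pos + 1, r.reference_end - 1))
    reads[split_i] = replace(
        _make_split(r, clip_pos),
        is_proper_pair=False,
        mate_chrom=partner.chrom,
        mate_pos=max(0, partner.pos + int(rng.integers(-200, 1))),
    )
    # reposition the true mate at the partner locus so both windows see the pair
    pair_name = r.name
    for j, other in enumerate(reads):
        if other.name == pair_name and j != split_i:
            reads[j] = replace(
                other,
                chrom=partner.chrom,
                pos=max(0, partner.pos + int(rng.integers(-200, 1))),
                is_proper_pair=False,
                mate_chrom=bp.chrom,
                mate_pos=reads[split_i].pos,
            )
            break


def regions_for_svs(
    svs: Sequence[SVRecord], pad: int = 500
) -> List[GenomicInterval]:
    """Merged breakpoint neighborhoods (±pad bp) covering all SVs."""
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for sv in svs:
        for bp in (sv.bp1, sv.bp2):
            by_chrom.setdefault(bp.chrom, []).append(
                (max(0, bp.pos - pad), bp.pos + pad)
            )
    merged: List[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        spans = sorted(by_chrom[chrom])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


def make_vaf_series(
    svs: Sequence[SVRecord],
    gradients: Sequence[float] = DEFAULT_GRADIENTS,
    replicates: int = 1,
    cfg: Optional[SpikeConfig] = None,
    depth: float = 200.0,
    region_pad: int = 500,
) -> List[SyntheticDataset]:
    """One spiked dataset per (VAF gradient, replicate).

    Child seeds are derived deterministically from (base seed, gradient
    index, replicate index), so the series is reproducible and replicates
    are independent.
    """
    cfg = cfg or SpikeConfig()
    if not all(0 < g <= 1 for g in gradients):
        raise ValueError("gradients must lie in (0, 1]")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if not svs:
        warnings.warn("empty SV list: datasets will carry empty truth sets")
    datasets: List[SyntheticDataset] = []
    regions = regions_for_svs(svs, pad=region_pad) or [
        GenomicInterval("chr1", 0, 10_000)
    ]
    for gi, g in enumerate(gradients):
        for ri in range(replicates):
            child = int(
                np.random.SeedSequence([cfg.seed, gi, ri]).generate_state(1)[0]
                % (2**31)
            )
            parts = []
            for rj, region in enumerate(regions):
                bg_cfg = replace(cfg, seed=child + rj, vaf=0.0)
                parts.append(generate_background(region, depth, bg_cfg))
            ds = SyntheticDataset(
                alignments=[a for p in parts for a in p.alignments],
                regions=list(regions),
                replicate_id=ri,
                vaf_gradient=g,
            )
            spike_cfg = replace(cfg, seed=child, vaf=g)
            for sv in svs:
                ds = spike_sv(ds, sv, spike_cfg)
            ds.replicate_id = ri
            ds.vaf_gradient = g
            datasets.append(ds)
    return datasets


# ---------------------------------------------------------------------------
# Labeled feature tables for exercising the decision model.

_INFORMATIVE = {
    # column: (FP mean, SD); the TP class is shifted by separation * SD
    "bp1_clip_count": (3.0, 2.0),
    "bp2_clip_count": (3.0, 2.0),
    "bp1_discordant_count": (2.0, 2.0),
    "bp2_discordant_count": (2.0, 2.0),
    "bp1_clip_len_mean": (8.0, 4.0),
    "bp2_clip_len_mean": (8.0, 4.0),
    "dv": (4.0, 3.0),
    "rv": (4.0, 3.0),
}


def synth_feature_table(
    n_true: int, n_false: int, separation: float, seed: int = 0
) -> Tuple[FeatureMatrix, np.ndarray]:
    """Random feature table in the extractor's schema with planted class signal.

    True-positive rows have their support and clip/discordant statistics
    shifted upward by ``separation`` standard deviations; at separation 0 the
    two classes are exchangeable.  Labels: 1 = TP, 0 = FP.
    """
    if n_true < 0 or n_false < 0:
        raise ValueError("counts must be non-negative")
    n = n_true + n_false
    if n == 0:
        raise ValueError("need at least one row")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    labels = np.concatenate([np.ones(n_true, dtype=int), np.zeros(n_false, dtype=int)])
    df = pd.DataFrame(0.0, index=pd.Index([f"sv{i}" for i in range(n)], name="id"), columns=SCHEMA)
    for i in (1, 2):
        df[f"bp{i}_depth"] = np.clip(rng.normal(500, 50, n), 50, None)
        df[f"bp{i}_mapq_min"] = np.clip(rng.normal(40, 8, n), 0, 60)
        df[f"bp{i}_mapq_max"] = 60.0
        df[f"bp{i}_mapq_mean"] = np.clip(rng.normal(57, 2, n), 0, 60)
        df[f"bp{i}_basequal_mean"] = np.clip(rng.normal(34, 2, n), 2, 40)
        df[f"bp{i}_repeat"] = (rng.random(n) < 0.1).astype(float)
    for col, (mu, sd) in _INFORMATIVE.items():
        shift = separation * sd * labels
        df[col] = np.clip(rng.normal(mu, sd, n) + shift, 0, None)
    for i in (1, 2):
        cnt = df[f"bp{i}_clip_count"]
        df[f"bp{i}_clip_len_min"] = np.where(cnt > 0, np.clip(df[f"bp{i}_clip_len_mean"] - 3, 1, None), 0.0)
        df[f"bp{i}_clip_len_max"] = np.where(cnt > 0, df[f"bp{i}_clip_len_mean"] + 3, 0.0)
    df["dv_rv_sum"] = df["dv"] + df["rv"]
    with np.errstate(invalid="ignore"):
        frac = np.where(df["dv_rv_sum"] > 0, df["rv"] / df["dv_rv_sum"].replace(0, np.nan), 0.0)
    df["rv_fraction"] = np.nan_to_num(frac)
    df["rv_fraction_imputed"] = (df["dv_rv_sum"] <= 0).astype(float)
    svtypes = rng.choice(["DEL", "DUP", "INV", "BND"], size=n, p=[0.3, 0.1, 0.1, 0.5])
    for t in ("DEL", "DUP", "INS", "INV", "BND"):
        df[f"svtype_{t}"] = (svtypes == t).astype(float)
    df["interchrom"] = ((svtypes == "BND") & (rng.random(n) < 0.5)).astype(float)
    perm = rng.permutation(n)
    df = df.iloc[perm]
    labels = labels[perm]
    return FeatureMatrix(data=df, schema_hash=schema_hash()), labels


# ---------------------------------------------------------------------------
# Text artifacts

def write_truth_tsv(truth: Sequence[TruthSV], path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(TRUTH_COLUMNS)
        for t in truth:
            r = t.record
            w.writerow(
                [r.id, r.svtype, r.bp1.chrom, r.bp1.pos, r.bp2.chrom, r.bp2.pos, t.vaf, t.support]
            )


def read_truth_tsv(path: str) -> List[TruthSV]:
    truth = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rec = SVRecord(
                id=row["id"],
                svtype=row["svtype"],
                bp1=Breakpoint(row["chrom1"], int(row["pos1"])),
                bp2=Breakpoint(row["chrom2"], int(row["pos2"])),
            )
            truth.append(TruthSV(record=rec, vaf=float(row["vaf"]), support=int(row["support"])))
    return truth


def write_dataset(ds: SyntheticDataset, sam_path: str, truth_path: str) -> None:
    from .io import write_sam

    write_sam(ds.alignments, sam_path, ds.contig_lengths())
    write_truth_tsv(ds.truth, truth_path)
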