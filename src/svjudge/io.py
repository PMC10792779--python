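"""Readers and writers for the VCF, BED, TSV and SAM dialects the framework touches.

VCF handling goes through :mod:`pysam`; two input dialects are understood:

``delly``
    INFO ``SVTYPE``/``END``/``CHR2``/``CT``/``MATEID``; FORMAT ``DV``/``RV``/
    ``DR``/``RR`` (first sample).  ``CT`` ("connection type") carries the
    breakend join class.
``generic``
    INFO ``SVTYPE``/``END`` plus standard breakend ALT strings; support
    fields are taken from FORMAT when present, otherwise marked missing.

All positions are converted between the 1-based VCF convention and the
package-internal 0-based convention here and nowhere else.
"""

from __future__ import annotations

import csv
import re
import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import pysam

from .types import (
    AlignedReadView,
    Breakpoint,
    GenomicInterval,
    RepeatTrack,
    SupportCounts,
    SVRecord,
)

TSV_COLUMNS = ["id", "svtype", "chrom1", "pos1", "chrom2", "pos2", "DV", "RV", "caller"]

_BND_RE = re.compile(
    r"^(?:(?P<t1>[A-Za-z.*]*)(?P<b1>[\[\]])(?P<chrom>[^:\[\]]+):(?P<pos>\d+)(?P=b1)"
    r"|(?P<b2>[\[\]])(?P<chrom2>[^:\[\]]+):(?P<pos2>\d+)(?P=b2)(?P<t2>[A-Za-z.*]*))$"
)


class VCFParseError(ValueError):
    pass


def parse_breakend_alt(alt: str) -> Tuple[str, int, str]:
    """Decode a VCF breakend ALT into (mate chrom, 0-based mate pos, orientation).

    The four bracket forms map onto the Delly ``CT`` join classes::

        t[p[  -> 3to5      t]p]  -> 3to3
        ]p]t  -> 5to3      [p[t  -> 5to5
    """
    m = _BND_RE.match(alt)
    if not m:
        raise VCFParseError(f"unparseable breakend ALT {alt!r}")
    if m.group("chrom") is not None:  # replacement text first: t[p[ or t]p]
        chrom, pos = m.group("chrom"), int(m.group("pos")) - 1
        orient = "3to5" if m.group("b1") == "[" else "3to3"
    else:  # bracket first: ]p]t or [p[t
        chrom, pos = m.group("chrom2"), int(m.group("pos2")) - 1
        orient = "5to3" if m.group("b2") == "]" else "5to5"
    return chrom, pos, orient


def encode_breakend_alt(bp2: Breakpoint, ref: str = "N") -> str:
    """Inverse of :func:`parse_breakend_alt`; unknown orientation defaults to 3to5."""
    p = f"{bp2.chrom}:{bp2.pos + 1}"
    orient = bp2.orientation or "3to5"
    return {
        "3to5": f"{ref}[{p}[",
        "3to3": f"{ref}]{p}]",
        "5to3": f"]{p}]{ref}",
        "5to5": f"[{p}[{ref}",
    }[orient]


def _get_info(rec, key):
    try:
        v = rec.info[key]
    except KeyError:
        return None
    if isinstance(v, tuple):
        v = v[0]
    return v


def _get_format_count(rec, key) -> Optional[int]:
    if not rec.samples:
        return None
    sample = rec.samples[0]
    if key not in sample:
        return None
    v = sample[key]
    if isinstance(v, tuple):
        v = v[0]
    if v is None:
        return None
    return int(v)


def _record_to_sv(rec, dialect: str) -> SVRecord:
    svtype = _get_info(rec, "SVTYPE")
    alt = rec.alts[0] if rec.alts else ""
    if svtype is None:
        if "[" in alt or "]" in alt:
            svtype = "BND"
        else:
            raise VCFParseError(f"record {rec.id or rec.pos} lacks SVTYPE")
    if svtype == "TRA":
        svtype = "BND"
    ct = _get_info(rec, "CT") if dialect == "delly" else None
    orientation = ct if ct in ("3to5", "5to3", "3to3", "5to5") else None

    pos1 = rec.pos - 1  # pysam rec.pos is 1-based
    chrom1 = rec.chrom
    if svtype == "BND" and ("[" in alt or "]" in alt):
        chrom2, pos2, alt_orient = parse_breakend_alt(alt)
        if orientation is None:
            orientation = alt_orient
    else:
        chrom2 = _get_info(rec, "CHR2") or chrom1
        # pysam surfaces INFO/END as rec.stop (0-based exclusive)
        pos2 = (rec.stop - 1) if rec.stop is not None else pos1

    support = SupportCounts(
        DV=_get_format_count(rec, "DV"),
        RV=_get_format_count(rec, "RV"),
        DR=_get_format_count(rec, "DR"),
        RR=_get_format_count(rec, "RR"),
    )
    flt = frozenset(rec.filter.keys())
    qual = float(rec.qual) if rec.qual is not None else None
    bp1 = Breakpoint(chrom1, pos1, orientation)
    bp2 = Breakpoint(chrom2, pos2, orientation)
    return SVRecord(
        id=rec.id or f"{chrom1}_{pos1}_{svtype}",
        svtype=svtype,
        bp1=bp1,
        bp2=bp2,
        caller=_get_info(rec, "CALLER") or "",
        support=support,
        qual=qual,
        filter_flags=flt,
    )


def read_sv_vcf(path: str, dialect: str = "delly") -> List[SVRecord]:
    """Read a structural-variant VCF into :class:`SVRecord` objects.

    Breakend (BND) mate records that reference each other through ``MATEID``
    are collapsed into a single record anchored at the mate with the smaller
    coordinate.  A BND whose partner is absent is kept, with its second
    breakpoint parsed from the ALT string, and a warning is emitted.
    """
    if dialect not in ("delly", "generic"):
        raise ValueError(f"unknown dialect {dialect!r}")
    records: List[SVRecord] = []
    bnd_buffer: Dict[str, tuple] = {}  # id -> (SVRecord, mateid)
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise VCFParseError(f"cannot open VCF {path}: {exc}") from exc
    with vf:
        for line_no, rec in enumerate(vf, start=1):
            try:
                sv = _record_to_sv(rec, dialect)
            except VCFParseError:
                raise
            except Exception as exc:
                raise VCFParseError(f"malformed VCF record #{line_no} in {path}: {exc}") from exc
            mateid = _get_info(rec, "MATEID")
            if sv.svtype == "BND" and mateid is not None:
                if mateid in bnd_buffer:
                    partner, _ = bnd_buffer.pop(mateid)
                    keep = min(
                        (partner, sv), key=lambda r: (r.bp1.chrom, r.bp1.pos, r.id)
                    )
                    records.append(keep)
                else:
                    bnd_buffer[sv.id] = (sv, mateid)
            else:
                records.append(sv)
    for sv, mateid in bnd_buffer.values():
        warnings.warn(
            f"breakend {sv.id} references absent mate {mateid}; keeping with "
            "bp2 parsed from ALT"
        )
        records.append(sv)
    return records


def read_bed_track(path: str) -> RepeatTrack:
    """Load a 3+ column BED (0-based half-open) into a point-queryable track."""
    track = RepeatTrack()
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{line_no}: fewer than 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start > end:
                raise ValueError(f"{path}:{line_no}: start {start} > end {end}")
            track.add(GenomicInterval(chrom, start, end))
    return track


def _contig_lengths(records: Sequence[SVRecord], pad: int = 1000) -> Dict[str, int]:
    lengths: Dict[str, int] = {}
    for rec in records:
        for bp in (rec.bp1, rec.bp2):
            lengths[bp.chrom] = max(lengths.get(bp.chrom, 0), bp.pos + pad)
    return lengths or {"chr1": pad}


def _build_vcf_header(records: Sequence[SVRecord]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom, length in sorted(_contig_lengths(records).items()):
        header.contigs.add(chrom, length=length)
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">')
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">')
    header.add_line('##INFO=<ID=CHR2,Number=1,Type=String,Description="Second chromosome">')
    header.add_line('##INFO=<ID=CT,Number=1,Type=String,Description="Breakend join class">')
    header.add_line('##INFO=<ID=CALLER,Number=1,Type=String,Description="Source caller">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DV,Number=1,Type=Integer,Description="High-quality variant pairs">')
    header.add_line('##FORMAT=<ID=RV,Number=1,Type=Integer,Description="High-quality variant junction reads">')
    header.add_line('##FORMAT=<ID=DR,Number=1,Type=Integer,Description="Reference pairs">')
    header.add_line('##FORMAT=<ID=RR,Number=1,Type=Integer,Description="Reference junction reads">')
    header.add_sample("SAMPLE")
    return header


def write_callset(records: Sequence[SVRecord], path: str, format: str = "vcf") -> None:
    """Write records as uncompressed VCF or as the package's 9-column TSV.

    VCF output restores 1-based coordinates; BND records are written as a
    single breakend line whose ALT encodes the partner locus and join class
    (an unknown join class serializes in the default ``t[p[`` form).
    """
    if format == "tsv":
        _write_callset_tsv(records, path)
        return
    if format != "vcf":
        raise ValueError(f"unknown format {format!r}")
    header = _build_vcf_header(records)
    with pysam.VariantFile(path, "w", header=header) as out:
        for sv in records:
            is_bnd = sv.svtype == "BND"
            rec = out.new_record(
                contig=sv.bp1.chrom,
                start=sv.bp1.pos,
                stop=(sv.bp1.pos + 1) if is_bnd else (sv.bp2.pos + 1),
            )
            rec.id = sv.id
            rec.ref = "N"
            if is_bnd:
                rec.alts = (encode_breakend_alt(sv.bp2),)
            else:
                rec.alts = (f"<{sv.svtype}>",)
                rec.stop = sv.bp2.pos + 1  # symbolic ALT resets rlen; restore END
                if sv.bp2.chrom != sv.bp1.chrom:
                    rec.info["CHR2"] = sv.bp2.chrom
            rec.info["SVTYPE"] = sv.svtype
            if sv.bp1.orientation is not None:
                rec.info["CT"] = sv.bp1.orientation
            if sv.caller:
                rec.info["CALLER"] = sv.caller
            if sv.qual is not None:
                rec.qual = sv.qual
            for flag in sorted(sv.filter_flags):
                if flag not in rec.header.filters:
                    # pysam requires declared filters; PASS is implicit
                    continue
                rec.filter.add(flag)
            for key in ("DV", "RV", "DR", "RR"):
                v = getattr(sv.support, key)
                if v is not None:
                    rec.samples["SAMPLE"][key] = v
            out.write(rec)


def _write_callset_tsv(records: Sequence[SVRecord], path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(TSV_COLUMNS)
        for sv in records:
            w.writerow(
                [
                    sv.id,
                    sv.svtype,
                    sv.bp1.chrom,
                    sv.bp1.pos,
                    sv.bp2.chrom,
                    sv.bp2.pos,
                    "." if sv.support.DV is None else sv.support.DV,
                    "." if sv.support.RV is None else sv.support.RV,
                    sv.caller,
                ]
            )


def read_callset_tsv(path: str) -> List[SVRecord]:
    """Read the package's 9-column callset TSV (0-based positions)."""
    records = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            support = SupportCounts(
                DV=None if row["DV"] in (".", "") else int(row["DV"]),
                RV=None if row["RV"] in (".", "") else int(row["RV"]),
            )
            records.append(
                SVRecord(
                    id=row["id"],
                    svtype=row["svtype"],
                    bp1=Breakpoint(row["chrom1"], int(row["pos1"])),
                    bp2=Breakpoint(row["chrom2"], int(row["pos2"])),
                    caller=row.get("caller", "") or "",
                    support=support,
                )
            )
    return records


# ---------------------------------------------------------------------------
# SAM-text alignment I/O (read-only consumption of BAM semantics; the
# simulator writes SAM so every artifact stays plain text).

def write_sam(reads: Sequence[AlignedReadView], path: str, contig_lengths: Dict[str, int]) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": int(l)} for c, l in sorted(contig_lengths.items())],
    }
    order = {c: i for i, c in enumerate(sorted(contig_lengths))}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for rv in sorted(reads, key=lambda r: (order.get(r.chrom, 1 << 30), r.pos)):
            a = pysam.AlignedSegment(out.header)
            a.query_name = rv.name
            a.reference_name = rv.chrom
            a.reference_start = rv.pos
            a.mapping_quality = rv.mapq
            a.cigarstring = "".join(f"{n}{op}" for op, n in rv.cigar)
            qlen = sum(n for op, n in rv.cigar if op in "MIS=X")
            a.query_sequence = "A" * qlen
            quals = list(rv.base_qualities)
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in quals)
            ) if len(quals) == qlen else pysam.qualitystring_to_array("I" * qlen)
            a.flag = (
                0x1
                | (0x2 if rv.is_proper_pair else 0)
                | (0x10 if rv.is_reverse else 0)
            )
            if rv.mate_chrom is not None:
                a.next_reference_name = rv.mate_chrom
                a.next_reference_start = rv.mate_pos
            out.write(a)


def read_sam(path: str) -> List[AlignedReadView]:
    reads = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            cigar = [
                ("MIDNSHP=XB"[op], n) for op, n in (a.cigartuples or [])
            ]
            reads.append(
                AlignedReadView(
                    name=a.query_name,
                    chrom=a.reference_name,
                    pos=a.reference_start,
                    mapq=a.mapping_quality,
                    cigar=cigar,
                    is_proper_pair=a.is_proper_pair,
                    is_reverse=a.is_reverse,
                    mate_chrom=a.next_reference_name,
                    mate_pos=a.next_reference_start if a.next_reference_start >= 0 else None,
                    base_qualities=list(a.query_qualities or ()),
                )
            )
    return reads
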