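"""Two-step filtering pipeline: panel filter, then the decision model.

Step one of the framework is an SV caller (Delly in the original workflow —
its VCF is consumed here, not produced).  Step two, implemented in this
module, restricts candidates to the clinical panel and removes false
positives with the trained random-forest bundle:

    read calls -> filter_to_panel -> build_feature_matrix -> predict
               -> retain probability >= threshold

Every input record is accounted for: it is either retained (with its TP
probability) or dropped with an explicit reason (``off-panel`` or
``model-FP``).
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import yaml
from intervaltree import IntervalTree

from . import io as svio
from .benchmark import DEFAULT_TOLERANCE_BP, match_calls
from .features import AlignmentIndex, FeatureConfig, build_feature_matrix
from .model import ConfusionMatrix, ModelBundle, compute_metrics, predict
from .simulate import TruthSV
from .types import GenomicInterval, RepeatTrack, SVRecord

logger = logging.getLogger("svjudge")


@dataclass
class PanelTarget:
    gene: str
    interval: GenomicInterval
    tier: str = ""


@dataclass
class PanelSV:
    """One clinically relevant SV: an (unordered) gene pair — identical
    genes denote an intragenic event — with its clinical evidence category."""

    gene_a: str
    gene_b: str
    svtype: str
    category: str  # prognostic | diagnostic | predictive

    @property
    def gene_key(self) -> frozenset:
        return frozenset((self.gene_a, self.gene_b))


class PanelDefinition:
    """Gene targets plus the clinically relevant SV list for one panel."""

    def __init__(self, targets: Sequence[PanelTarget], svs: Sequence[PanelSV] = ()):
        self.targets = list(targets)
        self.svs = list(svs)
        genes = {t.gene for t in self.targets}
        for sv in self.svs:
            missing = sv.gene_key - genes
            if missing:
                raise ValueError(
                    f"panel SV {sv.gene_a}-{sv.gene_b} references genes absent "
                    f"from the panel: {sorted(missing)}"
                )
        self._trees: Dict[str, IntervalTree] = {}
        for t in self.targets:
            self._trees.setdefault(t.interval.chrom, IntervalTree()).addi(
                t.interval.start, t.interval.end, t.gene
            )

    @property
    def genes(self) -> List[str]:
        return sorted({t.gene for t in self.targets})

    def gene_at(self, chrom: str, pos: int) -> Optional[str]:
        tree = self._trees.get(chrom)
        if tree is None:
            return None
        hits = tree[pos]
        return sorted(h.data for h in hits)[0] if hits else None

    def categories(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for sv in self.svs:
            out[sv.category] = out.get(sv.category, 0) + 1
        return out

    @classmethod
    def from_tsv(cls, genes_path: str, svs_path: Optional[str] = None) -> "PanelDefinition":
        targets = []
        with open(genes_path) as fh:
            for row in csv.DictReader(
                (l for l in fh if not l.startswith("#")), delimiter="\t"
            ):
                targets.append(
                    PanelTarget(
                        gene=row["gene"],
                        interval=GenomicInterval(
                            row["chrom"], int(row["start"]), int(row["end"])
                        ),
                        tier=row.get("tier", ""),
                    )
                )
        svs = []
        if svs_path:
            with open(svs_path) as fh:
                for row in csv.DictReader(
                    (l for l in fh if not l.startswith("#")), delimiter="\t"
                ):
                    svs.append(
                        PanelSV(
                            gene_a=row["gene_a"],
                            gene_b=row["gene_b"],
                            svtype=row["svtype"],
                            category=row["category"],
                        )
                    )
        return cls(targets, svs)

    @classmethod
    def default(cls) -> "PanelDefinition":
        """The shipped synthetic demonstration panel (27 genes, 61 SVs)."""
        pkg = resources.files("svjudge.data")
        with resources.as_file(pkg / "synthetic_panel_genes.tsv") as g, resources.as_file(
            pkg / "synthetic_panel_svs.tsv"
        ) as s:
            return cls.from_tsv(str(g), str(s))


def filter_to_panel(
    calls: Sequence[SVRecord], panel: PanelDefinition, strict: bool = False
) -> Tuple[List[SVRecord], List[SVRecord]]:
    """Partition calls into (on_panel, off_panel).

    Default mode: on-panel iff at least one breakpoint overlaps a panel
    target interval, or the record's gene pair matches a listed clinically
    relevant SV.  Strict mode additionally requires the event's gene pair
    (annotated or derived from breakpoint positions) to appear in the
    clinically relevant SV list.
    """
    listed = {sv.gene_key for sv in panel.svs}
    on: List[SVRecord] = []
    off: List[SVRecord] = []
    for call in calls:
        g1 = panel.gene_at(call.bp1.chrom, call.bp1.pos)
        g2 = panel.gene_at(call.bp2.chrom, call.bp2.pos)
        pair = frozenset(call.gene_pair) if call.gene_pair else None
        if strict:
            derived = frozenset(g for g in (g1, g2) if g) or None
            hit = (pair in listed) or (derived in listed)
        else:
            hit = (g1 is not None) or (g2 is not None) or (pair in listed)
        (on if hit else off).append(call)
    return on, off


@dataclass
class RunConfig:
    """Paths and knobs for one pipeline run; YAML-loadable."""

    calls: str
    alignments: str
    model_bundle: str
    repeats: Optional[str] = None
    panel_genes: Optional[str] = None
    panel_svs: Optional[str] = None
    dialect: str = "delly"
    strict_panel: bool = False
    tolerance_bp: int = DEFAULT_TOLERANCE_BP
    threshold: Optional[float] = None  # None = use the bundle's threshold
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class FilteredCallset:
    """Outcome of one two-step run; retained and dropped partition the input."""

    retained: List[SVRecord] = field(default_factory=list)
    probabilities: Dict[str, float] = field(default_factory=dict)
    panel_gene: Dict[str, str] = field(default_factory=dict)
    dropped: List[Tuple[SVRecord, str]] = field(default_factory=list)  # (record, reason)

    @property
    def n_input(self) -> int:
        return len(self.retained) + len(self.dropped)

    def drop_reasons(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for _, reason in self.dropped:
            out[reason] = out.get(reason, 0) + 1
        return out


def run_two_step(
    cfg: RunConfig,
    calls: Optional[Sequence[SVRecord]] = None,
    alignments: Optional[AlignmentIndex] = None,
    panel: Optional[PanelDefinition] = None,
    bundle: Optional[ModelBundle] = None,
    track: Optional[RepeatTrack] = None,
) -> FilteredCallset:
    """Run the two-step filter.  In-memory objects, when given, take
    precedence over the paths in ``cfg`` (the CLI passes paths only)."""
    logging.basicConfig(level=cfg.log_level)
    logger.info("two-step run: seed=%d config=%s", cfg.seed, cfg)
    if calls is None:
        calls = (
            svio.read_callset_tsv(cfg.calls)
            if cfg.calls.endswith(".tsv")
            else svio.read_sv_vcf(cfg.calls, dialect=cfg.dialect)
        )
    if panel is None:
        panel = (
            PanelDefinition.from_tsv(cfg.panel_genes, cfg.panel_svs)
            if cfg.panel_genes
            else PanelDefinition.default()
        )
    if bundle is None:
        bundle = ModelBundle.load(cfg.model_bundle)
    if track is None:
        track = svio.read_bed_track(cfg.repeats) if cfg.repeats else RepeatTrack()
    if alignments is None:
        alignments = AlignmentIndex.from_sam(cfg.alignments)

    on_panel, off_panel = filter_to_panel(calls, panel, strict=cfg.strict_panel)
    logger.info("panel filter: %d on-panel, %d off-panel", len(on_panel), len(off_panel))
    result = FilteredCallset(dropped=[(r, "off-panel") for r in off_panel])
    if not on_panel:
        return result

    matrix = build_feature_matrix(on_panel, alignments, track, FeatureConfig())
    preds = predict(bundle, matrix)
    threshold = bundle.threshold if cfg.threshold is None else cfg.threshold
    for rec in on_panel:
        p = float(preds.loc[rec.id, "probability"])
        if p >= threshold:
            result.retained.append(rec)
            result.probabilities[rec.id] = p
            gene = panel.gene_at(rec.bp1.chrom, rec.bp1.pos) or panel.gene_at(
                rec.bp2.chrom, rec.bp2.pos
            )
            if gene:
                result.panel_gene[rec.id] = gene
        else:
            result.dropped.append((rec, "model-FP"))
    assert result.n_input == len(calls)
    logger.info(
        "retained %d / %d calls (%s)", len(result.retained), len(calls),
        result.drop_reasons(),
    )
    return result


def evaluation_report(
    filtered: FilteredCallset,
    path: str,
    labels: Optional[Dict[str, str]] = None,
    truth: Optional[Sequence[TruthSV]] = None,
    panel: Optional[PanelDefinition] = None,
    tolerance_bp: int = DEFAULT_TOLERANCE_BP,
) -> dict:
    """Confusion matrix + the four metrics against expert labels or a truth
    set; truth-set mode also reports recall by gene.  Returns the report
    dict and writes it to ``path`` (JSON if the extension is .json, TSV
    otherwise)."""
    if labels is None and truth is None:
        raise ValueError("need labels or a truth set")
    report: dict = {}
    if labels is not None:
        all_records = list(filtered.retained) + [r for r, _ in filtered.dropped]
        known = [r for r in all_records if r.id in labels]
        if not known:
            raise ValueError("no overlap between callset ids and label ids")
        retained_ids = {r.id for r in filtered.retained}
        y_true = [1 if labels[r.id] == "TP" else 0 for r in known]
        y_pred = [1 if r.id in retained_ids else 0 for r in known]
        cm = ConfusionMatrix.from_labels(y_true, y_pred)
    else:
        mr = match_calls(filtered.retained, truth, tolerance_bp)
        dropped_records = [r for r, _ in filtered.dropped]
        unmatched = [t for t in truth if t.id in set(mr.unmatched_truth)]
        mr_dropped = match_calls(dropped_records, unmatched, tolerance_bp)
        cm = ConfusionMatrix(
            TP=len(mr.matched),
            FN=len(mr.unmatched_truth),
            FP=len(mr.unmatched_calls),
            TN=len(dropped_records) - len(mr_dropped.matched),
        )
        if panel is not None:
            per_gene: Dict[str, List[int]] = {}
            matched_truth = {tid for _, tid in mr.matched}
            for t in truth:
                gene = (
                    (t.record.gene_pair or (None,))[0]
                    or panel.gene_at(t.record.bp1.chrom, t.record.bp1.pos)
                    or "unassigned"
                )
                hit, tot = per_gene.get(gene, [0, 0])
                per_gene[gene] = [hit + (1 if t.id in matched_truth else 0), tot + 1]
            report["recall_by_gene"] = {
                g: {"detected": h, "total": n, "recall": h / n}
                for g, (h, n) in sorted(per_gene.items())
            }
    metrics = compute_metrics(cm)
    report["confusion_matrix"] = {"TP": cm.TP, "FP": cm.FP, "TN": cm.TN, "FN": cm.FN}
    report["metrics"] = metrics.as_dict()
    if path.endswith(".json"):
        with open(path, "w") as fh:
            json.dump(report, fh, indent=2)
    else:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            for k, v in {**report["confusion_matrix"], **report["metrics"]}.items():
                w.writerow([k, v])
            for gene, d in report.get("recall_by_gene", {}).items():
                w.writerow([f"recall:{gene}", d["detected"], d["total"], d["recall"]])
    return report
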