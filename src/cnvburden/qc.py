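"""Call-level quality control: size/probe filters, adjacent-call merging,
artefact-region flagging, and explicit exclusion lists.

The stages compose as filter -> merge -> flag by default (the order is a
pipeline argument); every disposition is recorded in a :class:`QcReport` so
downstream accounting can audit exactly which call fell where.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import groupby
from typing import Iterable, Sequence

from .intervals import (
    CnvCall,
    GenomicInterval,
    RegionSet,
    covered_fraction,
    min_distance_to_set,
)

__all__ = [
    "QcConfig",
    "QcReport",
    "filter_calls",
    "merge_adjacent",
    "flag_artifacts",
    "apply_exclusion_list",
    "run_qc",
]


@dataclass(frozen=True)
class QcConfig:
    """Thresholds for call-level QC.

    min_probes / min_length: inclusive lower bounds for keeping a call.
    max_gap_fraction: adjacent same-state calls merge when the gap is at
        most this fraction of the candidate joined span.
    artefact_overlap_fraction: calls covered by HLA/immunoglobulin regions
        at or above this fraction are flagged as probable artefacts.
    proximity_bp: calls within this distance of a telomere/centromere
        region are flagged.
    """

    min_probes: int = 10
    min_length: int = 100_000
    max_gap_fraction: float = 0.20
    artefact_overlap_fraction: float = 0.50
    proximity_bp: int = 500_000

    def __post_init__(self) -> None:
        if self.min_probes < 1 or self.min_length < 1 or self.proximity_bp < 0:
            raise ValueError("QC thresholds must be positive")
        for frac in (self.max_gap_fraction, self.artefact_overlap_fraction):
            if not (0 < frac <= 1):
                raise ValueError(f"fractions must be in (0,1], got {frac}")


@dataclass
class QcReport:
    """Per-stage counts and per-call disposition records."""

    stages: dict[str, dict[str, int]] = field(default_factory=dict)
    dispositions: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def record_stage(self, stage: str, n_in: int, n_kept: int) -> None:
        self.stages[stage] = {
            "in": n_in, "kept": n_kept, "removed": n_in - n_kept,
        }

    def record(self, stage: str, call: CnvCall, disposition: str,
               reason: str = "") -> None:
        self.dispositions.append({
            "stage": stage,
            "sample_id": call.sample_id,
            "chrom": call.interval.chrom,
            "start": call.interval.start,
            "end": call.interval.end,
            "cn_state": call.cn_state,
            "disposition": disposition,
            "reason": reason,
        })


def filter_calls(
    calls: Sequence[CnvCall], cfg: QcConfig, report: QcReport | None = None
) -> tuple[list[CnvCall], QcReport]:
    """Keep calls with at least ``min_probes`` probes and ``min_length`` bp
    (both inclusive); input order preserved."""
    report = report or QcReport()
    kept = []
    for c in calls:
        if c.n_probes < cfg.min_probes:
            report.record("filter", c, "removed",
                          f"n_probes {c.n_probes} < {cfg.min_probes}")
        elif c.length < cfg.min_length:
            report.record("filter", c, "removed",
                          f"length {c.length} < {cfg.min_length}")
        else:
            kept.append(c)
    report.record_stage("filter", len(calls), len(kept))
    return kept, report


def _merge_pair(a: CnvCall, b: CnvCall) -> CnvCall:
    return CnvCall(
        sample_id=a.sample_id,
        interval=GenomicInterval(a.interval.chrom, a.interval.start,
                                 max(a.interval.end, b.interval.end)),
        cn_state=a.cn_state,
        n_probes=a.n_probes + b.n_probes,
        source=a.source if a.source == b.source else f"{a.source}+{b.source}",
    )


def merge_adjacent(
    calls: Sequence[CnvCall], cfg: QcConfig, report: QcReport | None = None
) -> tuple[list[CnvCall], QcReport]:
    """Join adjacent same-state calls when the adjoining gap is at most
    ``max_gap_fraction`` of the full joined span.

    Applied left-to-right on position-sorted calls within each
    (sample, chromosome, copy-number state) group and iterated to a
    fixpoint, so cascades of mergeable neighbours collapse fully. Calls are
    never merged across samples, chromosomes or differing states.
    Overlapping same-state calls merge unconditionally (gap 0) with a
    warning. A merged call's probe count is the sum of its constituents.
    """
    report = report or QcReport()
    n_in = len(calls)

    def group_key(c: CnvCall):
        return (c.sample_id, c.interval.chrom, c.cn_state)

    out: list[CnvCall] = []
    for _, grp in groupby(sorted(calls, key=lambda c: (group_key(c), c.interval.start)),
                          key=group_key):
        pending = sorted(grp, key=lambda c: (c.interval.start, c.interval.end))
        changed = True
        while changed:
            changed = False
            merged: list[CnvCall] = []
            for c in pending:
                if not merged:
                    merged.append(c)
                    continue
                prev = merged[-1]
                gap = c.interval.start - prev.interval.end
                span = max(prev.interval.end, c.interval.end) - prev.interval.start
                if gap < 0:
                    report.warnings.append(
                        f"overlapping same-state calls for {c.sample_id} at "
                        f"{prev.interval} / {c.interval}; merged unconditionally"
                    )
                    merged[-1] = _merge_pair(prev, c)
                    changed = True
                elif gap / span <= cfg.max_gap_fraction:
                    merged[-1] = _merge_pair(prev, c)
                    changed = True
                else:
                    merged.append(c)
            pending = merged
        out.extend(pending)
    out.sort(key=lambda c: (c.sample_id, c.interval.chrom, c.interval.start))
    report.record_stage("merge", n_in, len(out))
    return out, report


def flag_artifacts(
    calls: Sequence[CnvCall],
    hla_ig: RegionSet,
    telo_cent: RegionSet,
    cfg: QcConfig,
    report: QcReport | None = None,
) -> tuple[list[CnvCall], list[CnvCall], QcReport]:
    """Split calls into (clean, flagged).

    A call is flagged as a probable artefact if it is covered by the
    HLA/immunoglobulin set at >= ``artefact_overlap_fraction``, or lies
    within ``proximity_bp`` of any telomere/centromere region (overlap
    counts as distance 0). Clean and flagged partition the input.
    """
    report = report or QcReport()
    clean: list[CnvCall] = []
    flagged: list[CnvCall] = []
    for c in calls:
        frac = covered_fraction(c.interval, hla_ig)
        dist = min_distance_to_set(c.interval, telo_cent)
        if frac >= cfg.artefact_overlap_fraction:
            flagged.append(c)
            report.record("artefact", c, "flagged",
                          f"HLA/IG overlap {frac:.3f}")
        elif dist <= cfg.proximity_bp:
            flagged.append(c)
            report.record("artefact", c, "flagged",
                          f"telomere/centromere distance {dist:.0f} bp")
        else:
            clean.append(c)
    report.record_stage("artefact", len(calls), len(clean))
    return clean, flagged, report


def apply_exclusion_list(
    calls: Sequence[CnvCall],
    excluded_keys: Iterable[tuple[str, str, int, int]],
    report: QcReport | None = None,
) -> tuple[list[CnvCall], QcReport]:
    """Remove calls whose (sample_id, chrom, start, end) key is listed.

    Stands in for manual curation of call plots: curated artefacts are
    supplied as an explicit, reproducible list. Keys that match no call
    produce a warning, not an error.
    """
    report = report or QcReport()
    keys = set(excluded_keys)
    kept = []
    seen: set = set()
    for c in calls:
        k = c.key()
        if k in keys:
            seen.add(k)
            report.record("exclusion", c, "removed", "exclusion list")
        else:
            kept.append(c)
    for k in keys - seen:
        report.warnings.append(f"exclusion key {k} matched no call")
    report.record_stage("exclusion", len(calls), len(kept))
    return kept, report


def run_qc(
    calls: Sequence[CnvCall],
    cfg: QcConfig,
    hla_ig: RegionSet | None = None,
    telo_cent: RegionSet | None = None,
    excluded_keys: Iterable[tuple] = (),
    order: str = "filter_then_merge",
) -> tuple[list[CnvCall], QcReport]:
    """Full QC composition: size/probe filter, adjacent merge, artefact
    flagging, exclusion list. ``order`` may be ``filter_then_merge``
    (default) or ``merge_then_filter``."""
    if order not in ("filter_then_merge", "merge_then_filter"):
        raise ValueError(f"unknown QC order {order!r}")
    report = QcReport()
    if order == "filter_then_merge":
        kept, _ = filter_calls(calls, cfg, report)
        kept, _ = merge_adjacent(kept, cfg, report)
    else:
        kept, _ = merge_adjacent(calls, cfg, report)
        kept, _ = filter_calls(kept, cfg, report)
    if hla_ig is not None or telo_cent is not None:
        hla_ig = hla_ig or RegionSet("hla_ig", [])
        telo_cent = telo_cent or RegionSet("telo_cent", [])
        kept, _, _ = flag_artifacts(kept, hla_ig, telo_cent, cfg, report)
    kept, _ = apply_exclusion_list(kept, excluded_keys, report)
    return kept, report
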