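"""Copy-number post-processing on CNVkit-style bins and segments.

Bin artifact removal, segment quality control, genome-wide burden (the
fraction of profiled length in gained/lost segments), chromosome-arm
calls, gene-level copy number with cross-region breakpoint exclusion, and
loss-of-heterozygosity calls from segment B-allele frequencies.

Threshold conventions: a segment is *gained* at log2 ratio > 0.3 and
*lost* at < -0.3; gene-level reporting uses the asymmetric > 0.4 / < -0.6
thresholds; LOH is BAF < 0.3 or > 0.7.  The burden denominator is the
summed length of segments passing the probe-count and variance QC only;
confident gain/loss calls (arms, genes) additionally require the log2
confidence interval to exclude 0 — applying the CI filter to the burden
denominator would leave an almost purely altered denominator on
exome-scale profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .model import (
    CopyNumberBin,
    CopyNumberSegment,
    GenomicInterval,
    GenomicIntervalSet,
    PmlseqError,
)

GAIN_LOG2 = 0.3
LOSS_LOG2 = -0.3
GENE_GAIN_LOG2 = 0.4
GENE_LOSS_LOG2 = -0.6
MIN_SEGMENT_PROBES = 10
MAX_BIVAR = 2.0
MIN_GENE_BINS = 3
MIN_GENE_SEGMENT_PROBES = 110
BAF_LOH_LOW = 0.3
BAF_LOH_HIGH = 0.7
BIN_ARTIFACT_LOG2 = -15.0


def clean_bins(bins: Iterable[CopyNumberBin]) -> list[CopyNumberBin]:
    """Drop bins with log2 copy ratio lower than -15 (capture artifacts)."""
    return [b for b in bins if b.log2 >= BIN_ARTIFACT_LOG2]


@dataclass
class SegmentQC:
    segment: CopyNumberSegment
    reasons: tuple[str, ...]  # empty => passing
    flagged_missing_ci: bool = False

    @property
    def passed(self) -> bool:
        return not self.reasons


def qc_segments(
    segments: Iterable[CopyNumberSegment],
    require_ci: bool = True,
) -> tuple[list[CopyNumberSegment], list[SegmentQC]]:
    """Partition segments into (passing, failing-with-reasons).

    A segment fails on fewer than 10 probes, biweight midvariance above 2,
    or — when ``require_ci`` — a log2 confidence interval containing 0.
    Segments without a CI are evaluated on the remaining criteria and
    flagged.
    """
    passing: list[CopyNumberSegment] = []
    failing: list[SegmentQC] = []
    for s in segments:
        reasons = []
        if s.n_probes < MIN_SEGMENT_PROBES:
            reasons.append("few_probes")
        if s.bivar is not None and s.bivar > MAX_BIVAR:
            reasons.append("high_bivar")
        flagged = not s.has_ci
        if require_ci and s.has_ci and s.ci_low <= 0.0 <= s.ci_high:
            reasons.append("ci_contains_zero")
        if reasons:
            failing.append(SegmentQC(s, tuple(reasons), flagged))
        else:
            passing.append(s)
    return passing, failing


def segment_is_confident(segment: CopyNumberSegment) -> bool:
    """True when the log2 CI excludes 0 (or no CI is available)."""
    if not segment.has_ci:
        return True
    return not (segment.ci_low <= 0.0 <= segment.ci_high)


@dataclass
class BurdenResult:
    gain_fraction: float
    loss_fraction: float
    total_length: int
    gain_length: int
    loss_length: int

    @property
    def total_fraction(self) -> float:
        return self.gain_fraction + self.loss_fraction

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "gain_fraction": self.gain_fraction,
                    "loss_fraction": self.loss_fraction,
                    "total_fraction": self.total_fraction,
                    "gain_length": self.gain_length,
                    "loss_length": self.loss_length,
                    "total_length": self.total_length,
                }
            ]
        )


def cna_burden(
    segments: Sequence[CopyNumberSegment],
    gain_log2: float = GAIN_LOG2,
    loss_log2: float = LOSS_LOG2,
) -> BurdenResult:
    """Genomic CNA burden: summed size of gained (log2 > 0.3) and lost
    (log2 < -0.3) segments over the summed size of all segments.

    Callers are expected to pass segments that survived the probe-count
    and variance QC.
    """
    total = sum(s.length for s in segments)
    if total == 0:
        raise PmlseqError("cna_burden: zero total segment length")
    gain = sum(s.length for s in segments if s.log2 > gain_log2)
    loss = sum(s.length for s in segments if s.log2 < loss_log2)
    return BurdenResult(
        gain_fraction=gain / total,
        loss_fraction=loss / total,
        total_length=total,
        gain_length=gain,
        loss_length=loss,
    )


@dataclass
class ArmCall:
    arm: str
    status: str  # {gained, lost, neutral}
    involved_fraction: float
    covered_length: int

    def to_row(self) -> dict:
        return {
            "arm": self.arm,
            "status": self.status,
            "involved_fraction": self.involved_fraction,
            "covered_length": self.covered_length,
        }


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def call_arms(
    segments: Sequence[CopyNumberSegment],
    arms: GenomicIntervalSet,
    gain_log2: float = GAIN_LOG2,
    loss_log2: float = LOSS_LOG2,
    min_fraction: float = 0.5,
) -> list[ArmCall]:
    """Call an arm gained/lost when more than half of its covered length
    lies in gained/lost segments.

    The denominator is the arm length covered by segments (targeted
    segments do not tile cytogenetic arms).  Gain/loss contributions
    require a confident segment (CI excluding 0 when present).  An arm
    cannot be both: the larger of the two fractions is evaluated.
    """
    calls = []
    for label in arms.labels:
        covered = gained = lost = 0
        for iv in arms.by_label(label):
            for s in segments:
                if s.chrom != iv.chrom:
                    continue
                ov = _overlap(s.start, s.end, iv.start, iv.end)
                if ov == 0:
                    continue
                covered += ov
                if segment_is_confident(s):
                    if s.log2 > gain_log2:
                        gained += ov
                    elif s.log2 < loss_log2:
                        lost += ov
        if covered == 0:
            calls.append(ArmCall(label, "neutral", 0.0, 0))
            continue
        frac_gain, frac_loss = gained / covered, lost / covered
        if frac_gain > min_fraction and frac_gain >= frac_loss:
            calls.append(ArmCall(label, "gained", frac_gain, covered))
        elif frac_loss > min_fraction:
            calls.append(ArmCall(label, "lost", frac_loss, covered))
        else:
            calls.append(ArmCall(label, "neutral", max(frac_gain, frac_loss), covered))
    return calls


@dataclass
class GeneCopyCall:
    gene: str
    region_id: str
    status: str  # {gain, loss, neutral, excluded}
    log2: Optional[float] = None
    n_bins: int = 0
    segment_probes: int = 0
    reason: str = ""

    def to_row(self) -> dict:
        return {
            "gene": self.gene,
            "region": self.region_id,
            "status": self.status,
            "log2": self.log2,
            "n_bins": self.n_bins,
            "segment_probes": self.segment_probes,
            "reason": self.reason,
        }


def _covering_segment(
    gene: GenomicInterval, segments: Sequence[CopyNumberSegment]
) -> Optional[CopyNumberSegment]:
    """Segment assigned to a gene: any-overlap, preferring the higher
    confidence segment (narrower CI, then more probes)."""
    overlapping = [
        s
        for s in segments
        if s.chrom == gene.chrom and _overlap(s.start, s.end, gene.start, gene.end) > 0
    ]
    if not overlapping:
        return None
    return min(overlapping, key=lambda s: (s.ci_width, -s.n_probes))


def _has_breakpoint(
    gene: GenomicInterval, segments: Sequence[CopyNumberSegment]
) -> bool:
    for s in segments:
        if s.chrom != gene.chrom:
            continue
        if gene.start < s.start < gene.end or gene.start < s.end < gene.end:
            return True
    return False


def call_gene_copy_number(
    regions: Mapping[str, tuple[Sequence[CopyNumberBin], Sequence[CopyNumberSegment]]],
    genes: GenomicIntervalSet,
    gain_log2: float = GENE_GAIN_LOG2,
    loss_log2: float = GENE_LOSS_LOG2,
    min_bins: int = MIN_GENE_BINS,
    min_segment_probes: int = MIN_GENE_SEGMENT_PROBES,
) -> dict[str, list[GeneCopyCall]]:
    """Per-region gene copy-number calls for one patient.

    A gene is eligible when at least ``min_bins`` bins overlap it and its
    covering segment has at least ``min_segment_probes`` probes.  Because
    segmentation breakpoints are imprecise, a gene overlapping a segment
    breakpoint in ANY region of the patient is excluded in all regions.
    Reporting thresholds: gain at log2 > 0.4, loss at log2 < -0.6,
    requiring a confident (CI excluding 0) segment.
    """
    gene_list = [iv for iv in genes]
    broken: set[str] = set()
    for _, (_, segs) in regions.items():
        for g in gene_list:
            if g.label in broken:
                continue
            if _has_breakpoint(g, segs):
                broken.add(g.label)

    out: dict[str, list[GeneCopyCall]] = {}
    for region_id, (bins, segs) in regions.items():
        calls = []
        for g in gene_list:
            n_bins = sum(
                1
                for b in bins
                if b.chrom == g.chrom and _overlap(b.start, b.end, g.start, g.end) > 0
            )
            seg = _covering_segment(g, segs)
            if g.label in broken:
                calls.append(
                    GeneCopyCall(g.label, region_id, "excluded", reason="breakpoint")
                )
                continue
            if seg is None:
                calls.append(
                    GeneCopyCall(g.label, region_id, "excluded", reason="no_segment")
                )
                continue
            if n_bins < min_bins or seg.n_probes < min_segment_probes:
                calls.append(
                    GeneCopyCall(
                        g.label,
                        region_id,
                        "excluded",
                        log2=seg.log2,
                        n_bins=n_bins,
                        segment_probes=seg.n_probes,
                        reason="ineligible",
                    )
                )
                continue
            confident = segment_is_confident(seg)
            if confident and seg.log2 > gain_log2:
                status = "gain"
            elif confident and seg.log2 < loss_log2:
                status = "loss"
            else:
                status = "neutral"
            calls.append(
                GeneCopyCall(
                    g.label,
                    region_id,
                    status,
                    log2=seg.log2,
                    n_bins=n_bins,
                    segment_probes=seg.n_probes,
                )
            )
        out[region_id] = calls
    return out


@dataclass
class LohCall:
    segment: CopyNumberSegment
    is_loh: bool
    flagged_missing_baf: bool = False

    def to_row(self) -> dict:
        return {
            "chromosome": self.segment.chrom,
            "start": self.segment.start,
            "end": self.segment.end,
            "baf": self.segment.baf,
            "is_loh": self.is_loh,
            "missing_baf": self.flagged_missing_baf,
        }


def call_loh(
    segments: Iterable[CopyNumberSegment],
    baf_low: float = BAF_LOH_LOW,
    baf_high: float = BAF_LOH_HIGH,
) -> list[LohCall]:
    """Loss of heterozygosity: segment B-allele frequency lower than 0.3
    or greater than 0.7.  Missing BAF means not LOH, flagged."""
    calls = []
    for s in segments:
        if s.baf is None:
            calls.append(LohCall(s, False, flagged_missing_baf=True))
        else:
            calls.append(LohCall(s, s.baf < baf_low or s.baf > baf_high))
    return calls


def biweight_midvariance(values: Sequence[float], c: float = 9.0) -> float:
    """Robust dispersion of bin log2 ratios (Tukey's biweight midvariance),
    the segment noise metric thresholded by QC."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        return 0.0
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return 0.0
    u = (x - med) / (c * mad)
    mask = np.abs(u) < 1
    if not mask.any():
        return 0.0
    d = x - med
    num = x.size * np.sum((d[mask] ** 2) * (1 - u[mask] ** 2) ** 4)
    den = np.sum((1 - u[mask] ** 2) * (1 - 5 * u[mask] ** 2)) ** 2
    return float(num / den) if den != 0 else 0.0
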