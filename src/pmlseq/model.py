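"""Core in-memory data model shared by every pipeline stage.

A :class:`VariantCall` is one normalized allele observation (one ALT allele
at one site) with caller provenance, quality metrics and annotations.
Copy-number data live in :class:`CopyNumberBin` / :class:`CopyNumberSegment`
using 0-based half-open coordinates; VCF positions stay 1-based.  The
multi-region unit of analysis is a :class:`PatientCohort` (patients ->
regions -> variant/bin/segment sets).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Iterator, Optional

from intervaltree import IntervalTree

#: (chrom, pos, ref, alt) -- the identity of an allele across callers,
#: regions and patients. pos is 1-based.
AlleleKey = tuple[str, int, str, str]

#: Numeric VariantCall fields that a FilterProfile rule may address.
METRIC_FIELDS = frozenset(
    {
        "vaf",
        "depth",
        "alt_forward",
        "alt_reverse",
        "ensemble_quality",
        "mapping_quality",
        "mean_mismatches",
        "mean_pos_in_read",
        "ms_length",
        "tlod",
        "fs_phred",
        "pop_af",
    }
)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: The six pyrimidine-context substitution classes used for spectrum
#: summaries (purine-reference SNVs are strand-collapsed onto these).
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


class PmlseqError(Exception):
    """Base class for pipeline errors."""


class ConfigError(PmlseqError):
    """Invalid configuration (unknown metric, empty target set, ...)."""


@dataclass
class VariantCall:
    """One ALT allele at one genomic site, with metrics and annotations.

    Metrics that a caller did not report are ``None`` ("missing"), never
    zero-filled; filters decide per-metric what missing means.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    vaf: Optional[float] = None
    depth: Optional[int] = None
    alt_forward: Optional[int] = None
    alt_reverse: Optional[int] = None
    ensemble_quality: Optional[float] = None
    mapping_quality: Optional[float] = None
    mean_mismatches: Optional[float] = None
    mean_pos_in_read: Optional[float] = None
    ms_length: Optional[float] = None
    tlod: Optional[float] = None
    fs_phred: Optional[float] = None
    callers: frozenset[str] = frozenset()
    pop_af: Optional[float] = None
    gene: Optional[str] = None
    is_cgc_tier1: bool = False
    in_cosmic: bool = False
    in_clinvar: bool = False
    is_hotspot_gene: bool = False
    effect_class: str = "unknown"  # {silent, non_silent, unknown}

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.vaf is not None and not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"vaf out of [0,1]: {self.vaf}")
        if self.depth is not None and self.depth < 0:
            raise ValueError(f"negative depth: {self.depth}")
        if (
            self.depth is not None
            and self.alt_forward is not None
            and self.alt_reverse is not None
            and self.alt_forward + self.alt_reverse > self.depth
        ):
            raise ValueError(
                f"alt strand counts exceed depth at {self.chrom}:{self.pos}"
            )
        if not isinstance(self.callers, frozenset):
            self.callers = frozenset(self.callers)

    @property
    def key(self) -> AlleleKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 == len(self.alt)

    @property
    def substitution_class(self) -> Optional[str]:
        """Pyrimidine-context class of an SNV, ``None`` for indels.

        Purine-reference substitutions are reported on the opposite strand
        (G>A counts as C>T, etc.), the convention of mutational-spectrum
        analyses.
        """
        if not self.is_snv:
            return None
        ref, alt = self.ref.upper(), self.alt.upper()
        if ref in ("G", "A"):
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        cls = f"{ref}>{alt}"
        return cls if cls in SUBSTITUTION_CLASSES else None

    def metric(self, name: str) -> Optional[float]:
        if name not in METRIC_FIELDS:
            raise ConfigError(f"unknown variant metric {name!r}")
        return getattr(self, name)

    def with_(self, **changes) -> "VariantCall":
        return replace(self, **changes)


def left_normalize(
    pos: int,
    ref: str,
    alt: str,
    get_base: Optional[Callable[[int], str]] = None,
) -> tuple[int, str, str]:
    """Left-align an allele so identity matching across callers is well
    defined.

    Repeatedly trims identical trailing bases, extending to the left with
    the reference base when an allele would become empty, then trims
    identical leading bases.  ``get_base(p)`` must return the reference
    base at 1-based position ``p`` of the variant's chromosome; without it
    only suffix/prefix trimming is performed (SNVs and already-normalized
    indels are unaffected).
    """
    ref, alt = ref.upper(), alt.upper()
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        elif ref[-1] == alt[-1] and pos > 1 and get_base is not None:
            b = get_base(pos - 1).upper()
            ref, alt, pos = b + ref[:-1], b + alt[:-1], pos - 1
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    return pos, ref, alt


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    label: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end <= start for {self.label or self.chrom}: [{self.start},{self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class GenomicIntervalSet:
    """Named intervals (targets, genes, chromosome arms) with fast overlap
    queries backed by per-chromosome interval trees."""

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):
        self.intervals: list[GenomicInterval] = list(intervals)
        self._trees: dict[str, IntervalTree] = {}
        for iv in self.intervals:
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def overlapping(self, chrom: str, start: int, end: int) -> list[GenomicInterval]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(start, end)]
        hits.sort(key=lambda iv: (iv.start, iv.end, iv.label))
        return hits

    def containing(self, chrom: str, pos0: int) -> list[GenomicInterval]:
        """Intervals containing the 0-based position ``pos0``."""
        return self.overlapping(chrom, pos0, pos0 + 1)

    @property
    def labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self.intervals:
            seen.setdefault(iv.label)
        return list(seen)

    def by_label(self, label: str) -> list[GenomicInterval]:
        return [iv for iv in self.intervals if iv.label == label]


@dataclass
class CopyNumberBin:
    chrom: str
    start: int
    end: int
    log2: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"bin end <= start: {self.chrom}:[{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CopyNumberSegment:
    chrom: str
    start: int
    end: int
    log2: float
    n_probes: int = 0
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    bivar: Optional[float] = None
    baf: Optional[float] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"segment end <= start: {self.chrom}:[{self.start},{self.end})"
            )
        if self.n_probes < 0:
            raise ValueError(f"negative n_probes: {self.n_probes}")
        if self.baf is not None and not (0.0 <= self.baf <= 1.0):
            raise ValueError(f"baf out of [0,1]: {self.baf}")
        if (
            self.ci_low is not None
            and self.ci_high is not None
            and not (self.ci_low <= self.log2 <= self.ci_high or
                     math.isclose(self.ci_low, self.log2) or
                     math.isclose(self.ci_high, self.log2))
        ):
            raise ValueError(
                f"log2 {self.log2} outside CI [{self.ci_low},{self.ci_high}]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def has_ci(self) -> bool:
        return self.ci_low is not None and self.ci_high is not None

    @property
    def ci_width(self) -> float:
        return (self.ci_high - self.ci_low) if self.has_ci else math.inf

    def contains(self, chrom: str, pos0: int) -> bool:
        return self.chrom == chrom and self.start <= pos0 < self.end


@dataclass
class RegionData:
    """One micro-dissected region: its variants and copy-number data.

    ``caller_variants`` holds the raw per-caller call sets before ensemble
    intersection; ``variants`` the current working set as the cascade
    progresses.  ``counts`` maps allele keys to (alt, depth) read counts
    from joint re-extraction across regions, used by the clonality model.
    """

    region_id: str
    variants: list[VariantCall] = field(default_factory=list)
    caller_variants: dict[str, list[VariantCall]] = field(default_factory=dict)
    bins: list[CopyNumberBin] = field(default_factory=list)
    segments: list[CopyNumberSegment] = field(default_factory=list)
    counts: Optional[dict[AlleleKey, tuple[int, int]]] = None


@dataclass
class Patient:
    patient_id: str
    regions: list[RegionData] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate region ids in patient {self.patient_id}")

    def region(self, region_id: str) -> RegionData:
        for r in self.regions:
            if r.region_id == region_id:
                return r
        raise KeyError(region_id)

    @property
    def region_ids(self) -> list[str]:
        return [r.region_id for r in self.regions]


@dataclass
class PatientCohort:
    patients: list[Patient] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate patient ids in cohort")

    def patient(self, patient_id: str) -> Patient:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    def __iter__(self) -> Iterator[Patient]:
        return iter(self.patients)


def sort_variants(variants: Iterable[VariantCall]) -> list[VariantCall]:
    """Deterministic (chrom, pos, ref, alt) ordering used by every stage."""
    return sorted(variants, key=lambda v: v.key)
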