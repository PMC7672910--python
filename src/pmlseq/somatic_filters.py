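"""The tumor-only somatic filtering cascade.

Raw ensemble variants are turned into candidate somatic mutations by a
fixed sequence of subset operations: population-germline removal with a
tier-1 cancer-gene rescue, VAF/LOH-based germline removal, named heuristic
artifact profiles, an ensemble-quality floor, and cross-patient recurrence
removal with a breast-cancer hotspot exemption.  A substitution-spectrum
summary over a low-VAF stratum provides the FFPE-damage diagnostic (C>T
dominated spectra in formalin-fixed tissue, C>A in frozen).

Comparator strictness follows the filters' published wording exactly:
"greater than" / "more than" / "lower than" are strict, "at least" /
"greater or equal" are inclusive.  Missing metrics default to *keep* — a
filter cannot fire on absent evidence.
"""

from __future__ import annotations

import operator
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .model import (
    METRIC_FIELDS,
    SUBSTITUTION_CLASSES,
    ConfigError,
    CopyNumberSegment,
    Patient,
    PatientCohort,
    VariantCall,
)

_OPS = {"<": operator.lt, ">": operator.gt, "<=": operator.le, ">=": operator.ge}

#: Genes whose recurrent mutations are exempt from cross-patient removal:
#: well-described breast-cancer hotspot genes.
DEFAULT_HOTSPOT_GENES = frozenset({"PIK3CA", "TP53", "GATA3"})


@dataclass(frozen=True)
class FilterRule:
    metric: str
    op: str  # one of < > <= >=
    threshold: float
    missing: str = "keep"  # {keep, drop}

    def __post_init__(self) -> None:
        if self.metric not in METRIC_FIELDS:
            raise ConfigError(f"unknown metric in filter rule: {self.metric!r}")
        if self.op not in _OPS:
            raise ConfigError(f"unknown comparator {self.op!r}")
        if self.missing not in ("keep", "drop"):
            raise ConfigError(f"missing_policy must be keep|drop, got {self.missing!r}")
        if not (self.threshold == self.threshold and abs(self.threshold) != float("inf")):
            raise ConfigError(f"non-finite threshold for {self.metric}")

    def passes(self, variant: VariantCall) -> bool:
        value = variant.metric(self.metric)
        if value is None:
            return self.missing == "keep"
        return _OPS[self.op](value, self.threshold)


@dataclass(frozen=True)
class FilterProfile:
    """A named conjunction of threshold comparisons on variant metrics."""

    name: str
    rules: tuple[FilterRule, ...] = ()

    def passes(self, variant: VariantCall) -> bool:
        return all(rule.passes(variant) for rule in self.rules)

    @classmethod
    def from_rules(
        cls, name: str, rules: Iterable[tuple[str, str, float]], missing: str = "keep"
    ) -> "FilterProfile":
        return cls(
            name,
            tuple(FilterRule(m, op, t, missing) for m, op, t in rules),
        )

    @classmethod
    def from_config(cls, name: str, spec: Sequence[Mapping]) -> "FilterProfile":
        """Build from a YAML-style list of {metric, op, threshold[, missing]}."""
        rules = []
        for entry in spec:
            rules.append(
                FilterRule(
                    metric=entry["metric"],
                    op=entry["op"],
                    threshold=float(entry["threshold"]),
                    missing=entry.get("missing", "keep"),
                )
            )
        return cls(name, tuple(rules))


# High-quality variants from the frozen test specimen: the "gold standard"
# call set definition.
GOLD_STANDARD_PROFILE = FilterProfile.from_rules(
    "gold_standard",
    [
        ("ensemble_quality", ">", 175),
        ("mean_mismatches", "<", 2.5),
        ("depth", ">=", 25),
        ("mean_pos_in_read", ">", 20),
        ("ms_length", "<", 5),
        ("vaf", ">", 0.14),
    ],
)

# FFPE benchmark profile: tolerant of lower coverage but stringent on the
# hallmarks of formalin damage (strand bias, read-position bias, low VAF).
FFPE_BENCHMARK_PROFILE = FilterProfile.from_rules(
    "ffpe_benchmark",
    [
        ("depth", ">=", 5),
        ("mapping_quality", ">", 45),
        ("mean_pos_in_read", ">", 15),
        ("mean_mismatches", "<", 2.5),
        ("ms_length", "<", 5),
        ("tlod", ">", 10),
        ("fs_phred", "<", 10),
        ("vaf", ">", 0.14),
    ],
)

# Permissive defaults standing in for the upstream tumor-only caller
# defaults; fully overridable from config.
INITIAL_PROFILE = FilterProfile.from_rules(
    "initial",
    [
        ("depth", ">=", 4),
        ("ensemble_quality", ">", 0),
    ],
)

BUILTIN_PROFILES = {
    p.name: p
    for p in (GOLD_STANDARD_PROFILE, FFPE_BENCHMARK_PROFILE, INITIAL_PROFILE)
}


def apply_heuristic_profile(
    variants: Iterable[VariantCall], profile: FilterProfile
) -> list[VariantCall]:
    """Keep a variant iff every rule of the profile passes."""
    return [v for v in variants if profile.passes(v)]


def filter_population_germline(
    variants: Iterable[VariantCall], maf_threshold: float = 1e-3
) -> list[VariantCall]:
    """Remove common population variants (max MAF > threshold) unless they
    are rescued as tier-1 cancer-gene mutations seen in COSMIC or ClinVar.

    A missing ``pop_af`` is treated as rare (kept).
    """
    kept = []
    for v in variants:
        common = v.pop_af is not None and v.pop_af > maf_threshold
        rescued = v.is_cgc_tier1 and (v.in_cosmic or v.in_clinvar)
        if common and not rescued:
            continue
        kept.append(v)
    return kept


def _loh_lookup(segments: Sequence[CopyNumberSegment], loh_calls) -> list:
    from .cna_profile import LohCall  # local import; cna_profile is independent

    if loh_calls and not isinstance(loh_calls[0], LohCall):
        raise TypeError("loh_calls must come from cna_profile.call_loh")
    return list(loh_calls)


def filter_vaf_loh_germline(
    variants: Iterable[VariantCall],
    segments: Sequence[CopyNumberSegment],
    loh_calls,
    vaf_threshold: float = 0.9,
) -> list[VariantCall]:
    """Remove likely germline variants: VAF >= threshold in a non-LOH
    segment (or in no segment at all).

    In a segment with loss of heterozygosity a true somatic or germline
    allele can legitimately drift to VAF ~1, so LOH segments are exempt.
    ``loh_calls`` must be the output of :func:`pmlseq.cna_profile.call_loh`
    on the same segments.
    """
    calls = _loh_lookup(segments, loh_calls)
    loh_segments = [c.segment for c in calls if c.is_loh]
    kept = []
    for v in variants:
        if v.vaf is None or v.vaf < vaf_threshold:
            kept.append(v)
            continue
        in_loh = any(s.contains(v.chrom, v.pos - 1) for s in loh_segments)
        if in_loh:
            kept.append(v)
    return kept


def filter_quality_floor(
    variants: Iterable[VariantCall], floor: float = 115.0
) -> list[VariantCall]:
    """Exclude variants with ensemble quality score lower than ``floor``
    (the F-optimal operating point for low-input blunt-end libraries).
    Missing scores are kept."""
    return [
        v
        for v in variants
        if v.ensemble_quality is None or v.ensemble_quality >= floor
    ]


def filter_cross_patient_recurrent(
    cohort: PatientCohort,
    hotspot_genes: frozenset[str] = DEFAULT_HOTSPOT_GENES,
) -> PatientCohort:
    """Remove any allele observed in two or more patients — in a cohort of
    unrelated patients a recurrent identical allele is almost surely a
    residual germline variant or a recurrent artifact — except in the
    named hotspot genes."""
    patients_by_key: dict = {}
    for patient in cohort:
        seen = set()
        for region in patient.regions:
            for v in region.variants:
                seen.add(v.key)
        for key in seen:
            patients_by_key.setdefault(key, set()).add(patient.patient_id)
    recurrent = {k for k, pats in patients_by_key.items() if len(pats) >= 2}

    new_patients = []
    for patient in cohort:
        new_regions = []
        for region in patient.regions:
            kept = [
                v
                for v in region.variants
                if v.key not in recurrent or (v.gene in hotspot_genes)
            ]
            new_regions.append(
                type(region)(
                    region_id=region.region_id,
                    variants=kept,
                    caller_variants=region.caller_variants,
                    bins=region.bins,
                    segments=region.segments,
                    counts=region.counts,
                )
            )
        new_patients.append(Patient(patient.patient_id, new_regions))
    return PatientCohort(new_patients)


@dataclass
class SpectrumSummary:
    """Counts and fractions over the six pyrimidine-context substitution
    classes, restricted to SNVs with VAF below ``vaf_max``."""

    vaf_max: float
    counts: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in SUBSTITUTION_CLASSES}
    )

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def undefined(self) -> bool:
        return self.total == 0

    @property
    def fractions(self) -> Optional[dict[str, float]]:
        if self.undefined:
            return None
        total = self.total
        return {c: n / total for c, n in self.counts.items()}

    @property
    def dominant_class(self) -> Optional[str]:
        if self.undefined:
            return None
        return max(SUBSTITUTION_CLASSES, key=lambda c: self.counts[c])

    def to_frame(self):
        import pandas as pd

        fr = self.fractions or {c: float("nan") for c in SUBSTITUTION_CLASSES}
        return pd.DataFrame(
            {
                "class": list(SUBSTITUTION_CLASSES),
                "count": [self.counts[c] for c in SUBSTITUTION_CLASSES],
                "fraction": [fr[c] for c in SUBSTITUTION_CLASSES],
            }
        )


def substitution_spectrum(
    variants: Iterable[VariantCall], vaf_max: float = 0.05
) -> SpectrumSummary:
    """Substitution spectrum of the low-VAF stratum (``vaf < vaf_max``).

    Indels and variants with missing VAF are ignored; purine-reference
    SNVs are strand-collapsed (G>A counts as C>T).
    """
    summary = SpectrumSummary(vaf_max=vaf_max)
    for v in variants:
        cls = v.substitution_class
        if cls is None or v.vaf is None or v.vaf >= vaf_max:
            continue
        summary.counts[cls] += 1
    return summary
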