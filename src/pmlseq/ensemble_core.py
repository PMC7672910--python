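"""Two-caller ensemble harmonization.

Without a matched normal, single-caller tumor-only call sets are dominated
by artifacts; only variants reported by both callers are considered
(ensemble calling).  The raw ensemble is then restricted to padded target
regions overlapping annotated genes, panel-of-normals entries are
subtracted, and a permissive initial profile is applied.  Every gate is a
pure subset operation, and the provenance counter records the set size
after each one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .model import (
    AlleleKey,
    ConfigError,
    GenomicIntervalSet,
    VariantCall,
    sort_variants,
)
from .somatic_filters import INITIAL_PROFILE, FilterProfile, apply_heuristic_profile

# Metrics merged across callers on intersection: caller1's value wins,
# caller2 fills gaps (e.g. tumor log-odds is reported by only one caller).
_MERGE_FIELDS = (
    "vaf",
    "depth",
    "alt_forward",
    "alt_reverse",
    "mapping_quality",
    "mean_mismatches",
    "mean_pos_in_read",
    "ms_length",
    "tlod",
    "fs_phred",
    "pop_af",
    "gene",
    "effect_class",
)


@dataclass
class EnsembleSet:
    """Variants called by both callers, with gate-by-gate provenance."""

    variants: list[VariantCall] = field(default_factory=list)
    provenance: dict[str, int] = field(default_factory=dict)

    def record(self, gate: str, variants: list[VariantCall]) -> list[VariantCall]:
        self.provenance[gate] = len(variants)
        return variants


def _dedupe(variants: Iterable[VariantCall]) -> dict[AlleleKey, VariantCall]:
    """Collapse duplicate keys within one caller, keeping the
    higher-quality record."""
    best: dict[AlleleKey, VariantCall] = {}
    for v in variants:
        prev = best.get(v.key)
        if prev is None:
            best[v.key] = v
            continue
        q_new = v.ensemble_quality if v.ensemble_quality is not None else float("-inf")
        q_old = (
            prev.ensemble_quality if prev.ensemble_quality is not None else float("-inf")
        )
        if q_new > q_old:
            best[v.key] = v
    return best


def _merge(v1: VariantCall, v2: VariantCall) -> VariantCall:
    changes: dict = {"callers": v1.callers | v2.callers}
    q1, q2 = v1.ensemble_quality, v2.ensemble_quality
    if q1 is None:
        changes["ensemble_quality"] = q2
    elif q2 is not None:
        changes["ensemble_quality"] = max(q1, q2)
    for name in _MERGE_FIELDS:
        if getattr(v1, name) is None and getattr(v2, name) is not None:
            changes[name] = getattr(v2, name)
    for name in ("is_cgc_tier1", "in_cosmic", "in_clinvar", "is_hotspot_gene"):
        changes[name] = getattr(v1, name) or getattr(v2, name)
    return v1.with_(**changes)


def intersect_callers(
    set1: Sequence[VariantCall], set2: Sequence[VariantCall]
) -> EnsembleSet:
    """Retain alleles called by both callers.

    Identity is the normalized allele key (chrom, pos, ref, alt); inputs
    must already be left-aligned with multiallelic records split (the
    readers do this).  The retained record carries caller1's count-type
    metrics, caller2 fills metrics caller1 did not report, and the
    ensemble quality is the maximum across callers.
    """
    d1, d2 = _dedupe(set1), _dedupe(set2)
    merged = [_merge(d1[k], d2[k]) for k in d1.keys() & d2.keys()]
    ens = EnsembleSet(variants=sort_variants(merged))
    ens.provenance["caller1"] = len(set1)
    ens.provenance["caller2"] = len(set2)
    ens.provenance["ensemble"] = len(ens.variants)
    return ens


def apply_target_mask(
    variants: Iterable[VariantCall],
    targets: GenomicIntervalSet,
    genes: GenomicIntervalSet,
    pad: int = 10,
) -> list[VariantCall]:
    """Keep variants within ``pad`` bases of a target interval that
    overlaps an annotated gene."""
    if len(targets) == 0:
        raise ConfigError("empty target set: pipeline misconfiguration")
    kept = []
    for v in variants:
        pos0 = v.pos - 1
        for t in targets.overlapping(v.chrom, pos0 - pad, pos0 + pad + 1):
            if not (t.start - pad <= pos0 < t.end + pad):
                continue
            if genes.overlapping(t.chrom, t.start, t.end):
                kept.append(v)
                break
    return kept


def subtract_panel_of_normals(
    variants: Iterable[VariantCall],
    pon: Iterable[VariantCall] | Iterable[AlleleKey],
) -> list[VariantCall]:
    """Remove alleles present in the panel of normals (recurrent artifacts
    and common germline variants seen across unrelated normal samples)."""
    pon_keys = {
        v.key if isinstance(v, VariantCall) else tuple(v) for v in pon
    }
    return [v for v in variants if v.key not in pon_keys]


def apply_initial_filters(
    variants: Iterable[VariantCall],
    profile: Optional[FilterProfile] = None,
) -> list[VariantCall]:
    """Permissive first-pass gate mirroring upstream tumor-only caller
    defaults; same threshold engine as the heuristic profiles."""
    return apply_heuristic_profile(variants, profile or INITIAL_PROFILE)


def build_raw_ensemble(
    set1: Sequence[VariantCall],
    set2: Sequence[VariantCall],
    targets: GenomicIntervalSet,
    genes: GenomicIntervalSet,
    pon: Iterable[VariantCall] | Iterable[AlleleKey] = (),
    pad: int = 10,
    initial_profile: Optional[FilterProfile] = None,
) -> EnsembleSet:
    """Full harmonization: intersection -> initial filters -> target mask
    -> PoN subtraction, with provenance counts after each gate."""
    ens = intersect_callers(set1, set2)
    variants = ens.record(
        "initial", apply_initial_filters(ens.variants, initial_profile)
    )
    variants = ens.record(
        "target_mask", apply_target_mask(variants, targets, genes, pad=pad)
    )
    variants = ens.record("pon", subtract_panel_of_normals(variants, pon))
    ens.variants = variants
    return ens
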