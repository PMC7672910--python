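"""The end-to-end filtering cascade over a multi-region cohort.

Fixed stage order (each stage a pure subset of the previous):

  caller intersection -> initial filters -> target mask -> panel of
  normals -> population germline (tier-1 rescue) -> VAF/LOH germline ->
  heuristic artifact profile -> ensemble-quality floor -> cross-region
  germline propagation -> cross-patient recurrence removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .cna_profile import call_loh, qc_segments
from .ensemble_core import build_raw_ensemble
from .model import (
    AlleleKey,
    GenomicIntervalSet,
    Patient,
    PatientCohort,
    RegionData,
    VariantCall,
)
from .multiregion_clonality import propagate_germline_exclusion
from .somatic_filters import (
    DEFAULT_HOTSPOT_GENES,
    FFPE_BENCHMARK_PROFILE,
    FilterProfile,
    filter_cross_patient_recurrent,
    filter_population_germline,
    filter_quality_floor,
    filter_vaf_loh_germline,
)


@dataclass
class CascadeResult:
    cohort: PatientCohort
    raw_ensemble: dict[tuple[str, str], list[VariantCall]] = field(default_factory=dict)
    removed: dict[tuple[str, str], list[VariantCall]] = field(default_factory=dict)
    provenance: dict[tuple[str, str], dict[str, int]] = field(default_factory=dict)

    def final_variants(self, patient_id: str, region_id: str) -> list[VariantCall]:
        return self.cohort.patient(patient_id).region(region_id).variants

    def all_removed(self) -> list[VariantCall]:
        out = []
        for variants in self.removed.values():
            out.extend(variants)
        return out


def run_filter_cascade(
    cohort: PatientCohort,
    targets: GenomicIntervalSet,
    genes: GenomicIntervalSet,
    pon: Iterable[AlleleKey] = (),
    profile: FilterProfile = FFPE_BENCHMARK_PROFILE,
    quality_floor: float = 115.0,
    initial_profile: Optional[FilterProfile] = None,
    hotspot_genes: frozenset[str] = DEFAULT_HOTSPOT_GENES,
    maf_threshold: float = 1e-3,
    pad: int = 10,
) -> CascadeResult:
    """Run the full cascade; regions must carry two caller call sets in
    ``caller_variants``.  Returns the filtered cohort plus, per region,
    the raw ensemble set, the removed variants and gate-by-gate counts."""
    pon = list(pon)
    raw_ensemble: dict[tuple[str, str], list[VariantCall]] = {}
    provenance: dict[tuple[str, str], dict[str, int]] = {}

    staged_patients = []
    for patient in cohort:
        staged_regions = []
        for region in patient.regions:
            labels = sorted(region.caller_variants)
            if len(labels) != 2:
                raise ValueError(
                    f"region {region.region_id} needs exactly two caller call "
                    f"sets, found {labels}"
                )
            ens = build_raw_ensemble(
                region.caller_variants[labels[0]],
                region.caller_variants[labels[1]],
                targets,
                genes,
                pon=pon,
                pad=pad,
                initial_profile=initial_profile,
            )
            key = (patient.patient_id, region.region_id)
            raw_ensemble[key] = list(ens.variants)
            prov = dict(ens.provenance)

            variants = filter_population_germline(ens.variants, maf_threshold)
            prov["population_germline"] = len(variants)

            loh = call_loh(region.segments)
            variants = filter_vaf_loh_germline(variants, region.segments, loh)
            prov["vaf_loh_germline"] = len(variants)

            variants = [v for v in variants if profile.passes(v)]
            prov[f"profile_{profile.name}"] = len(variants)

            variants = filter_quality_floor(variants, quality_floor)
            prov["quality_floor"] = len(variants)

            provenance[key] = prov
            staged_regions.append(
                RegionData(
                    region_id=region.region_id,
                    variants=variants,
                    caller_variants=region.caller_variants,
                    bins=region.bins,
                    segments=region.segments,
                    counts=region.counts,
                )
            )
        staged_patients.append(Patient(patient.patient_id, staged_regions))

    propagated = PatientCohort(
        [propagate_germline_exclusion(p) for p in staged_patients]
    )
    for patient in propagated:
        for region in patient.regions:
            provenance[(patient.patient_id, region.region_id)]["cross_region"] = len(
                region.variants
            )

    final = filter_cross_patient_recurrent(propagated, hotspot_genes)
    removed: dict[tuple[str, str], list[VariantCall]] = {}
    for patient in final:
        for region in patient.regions:
            key = (patient.patient_id, region.region_id)
            provenance[key]["cross_patient"] = len(region.variants)
            final_keys = {v.key for v in region.variants}
            removed[key] = [
                v for v in raw_ensemble[key] if v.key not in final_keys
            ]
    return CascadeResult(
        cohort=final,
        raw_ensemble=raw_ensemble,
        removed=removed,
        provenance=provenance,
    )


def region_burden_segments(region: RegionData):
    """Segments entering the burden denominator: probe-count and variance
    QC only (no CI criterion)."""
    passing, _ = qc_segments(region.segments, require_ci=False)
    return passing
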