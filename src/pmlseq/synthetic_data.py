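"""Seeded generator of multi-patient, multi-region cohorts with known
ground truth.

The generator emulates the inputs the post-processing stack consumes, at
desk scale, with a truth bundle for every emitted record:

* germline variants at population frequencies (mostly common, a few rare;
  ~10% homozygous), shared by all regions of a patient;
* clonal somatic SNVs/indels inherited along a rooted clone tree over the
  patient's regions;
* fixation artifacts: low-VAF (Beta-distributed, mass below 5%),
  one-sided strand support, substitution spectrum dominated by C>T in
  FFPE mode (weight 0.53) or C>A in frozen mode (0.52), poor concordance
  between the two emulated callers;
* segmented copy-number profiles realizing a configured event list (arm
  losses/gains with LOH via B-allele frequency shifts, focal events) as
  bins + segments with probe counts, confidence intervals and biweight
  midvariance;
* per-region (alt, depth) count tables at every germline/somatic site for
  the clonality model, drawn at a deeper "joint re-extraction" coverage
  with a small residual error rate at absent sites.

The genome model is synthetic (default 2 chromosomes x 50 Mb with arm
boundaries at the midpoint); reference bases are a deterministic hash of
position so no sequence is stored.  One root seed drives everything, with
per-patient/per-region substreams, so identical (seed, config) produce
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .cna_profile import biweight_midvariance
from .formats_io import (
    write_bed,
    write_bins,
    write_counts,
    write_segments,
    write_variants,
)
from .model import (
    AlleleKey,
    CopyNumberBin,
    CopyNumberSegment,
    GenomicInterval,
    GenomicIntervalSet,
    Patient,
    PatientCohort,
    PmlseqError,
    RegionData,
    VariantCall,
)

_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

FFPE_SPECTRUM = {
    "C>A": 0.12, "C>G": 0.05, "C>T": 0.53, "T>A": 0.08, "T>C": 0.15, "T>G": 0.07,
}
FROZEN_SPECTRUM = {
    "C>A": 0.52, "C>G": 0.06, "C>T": 0.15, "T>A": 0.07, "T>C": 0.13, "T>G": 0.07,
}

#: Named cancer genes planted on the synthetic genome (gene index within
#: chromosome -> symbol).  TP53/GATA3/PIK3CA are the hotspot-exempt trio.
CANCER_GENES = {
    ("chr1", 3): "TP53",
    ("chr1", 10): "GATA3",
    ("chr2", 5): "PIK3CA",
    ("chr2", 20): "ERBB2",
    ("chr2", 30): "FGFR1",
}

DEFAULT_CNA_EVENTS = [
    {"arm": "1p", "log2": -0.5, "fraction": 0.8, "baf": 0.2},
    {"chrom": "chr2", "start_target": 600, "end_target": 720, "log2": 0.8},
]


@dataclass
class SimulationConfig:
    """All dials of the generator; defaults are the study conditions the
    rest of the package is verified under."""

    seed: int = 0
    mode: str = "ffpe"  # {ffpe, frozen} -- artifact substitution spectrum
    n_patients: int = 3
    regions_per_patient: int = 3
    mean_coverage: float = 80.0
    counts_coverage: float = 200.0  # joint re-extraction depth
    count_error_rate: float = 0.02  # error rate at absent sites (the model's e)

    n_germline: int = 100
    n_truncal: int = 30
    n_shared: int = 10  # per internal (non-root) tree node
    n_private: int = 8  # per leaf
    n_artifacts: int = 10000
    indel_fraction: float = 0.08
    germline_hom_fraction: float = 0.10
    somatic_vaf_low: float = 0.25
    somatic_vaf_high: float = 0.55

    artifact_vaf_alpha: float = 1.5
    artifact_vaf_beta: float = 70.0
    concordance_true: float = 0.97
    concordance_artifact: float = 0.15
    quality_true_mean: float = 200.0
    quality_true_sd: float = 40.0
    quality_artifact_mean: float = 60.0
    quality_artifact_sd: float = 30.0

    # genome model
    chroms: tuple[str, ...] = ("chr1", "chr2")
    chrom_length: int = 50_000_000
    n_targets_per_chrom: int = 1500
    target_length: int = 250
    targets_per_gene: int = 10

    # population catalog / panel of normals
    n_population_sites: int = 1500
    population_common_fraction: float = 0.95
    pon_catalog_fraction: float = 0.90
    artifact_pool_size: int = 300
    artifact_pool_fraction: float = 0.10

    # copy number
    bin_noise_sd: float = 0.3
    cna_events: list = field(default_factory=lambda: [dict(e) for e in DEFAULT_CNA_EVENTS])

    caller_labels: tuple[str, str] = ("vardict", "mutect2")
    tree_spec: Optional[dict] = None  # explicit clone tree (see parse_tree_spec)

    def __post_init__(self) -> None:
        if self.mode not in ("ffpe", "frozen"):
            raise PmlseqError(f"mode must be ffpe|frozen, got {self.mode!r}")
        if self.regions_per_patient < 1:
            raise PmlseqError("regions_per_patient must be >= 1")
        for name in ("concordance_true", "concordance_artifact",
                     "germline_hom_fraction", "artifact_pool_fraction",
                     "population_common_fraction", "pon_catalog_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise PmlseqError(f"{name} must lie in [0,1], got {v}")
        for name in ("n_germline", "n_truncal", "n_shared", "n_private",
                     "n_artifacts"):
            if getattr(self, name) < 0:
                raise PmlseqError(f"{name} must be >= 0")

    @property
    def spectrum(self) -> dict[str, float]:
        return FFPE_SPECTRUM if self.mode == "ffpe" else FROZEN_SPECTRUM

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("chroms", "caller_labels"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["chroms"] = list(self.chroms)
        data["caller_labels"] = list(self.caller_labels)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


class GenomeModel:
    """Deterministic synthetic genome: targets, genes, arms, reference
    bases.  Positions 1..target_length within a target are split into a
    variant zone (first 50 bp, germline + somatic) and an artifact zone
    (the rest) so truth classes can never collide."""

    VARIANT_ZONE = 50

    def __init__(self, config: SimulationConfig):
        self.config = config
        self.chroms = list(config.chroms)
        self.contigs = {c: config.chrom_length for c in self.chroms}
        spacing = config.chrom_length // (config.n_targets_per_chrom + 1)
        self._targets: list[GenomicInterval] = []
        for c in self.chroms:
            for i in range(config.n_targets_per_chrom):
                start = (i + 1) * spacing
                self._targets.append(
                    GenomicInterval(c, start, start + config.target_length,
                                    label=f"target_{c}_{i:05d}")
                )
        self._genes: list[GenomicInterval] = []
        per = config.targets_per_gene
        for c in self.chroms:
            ctargets = [t for t in self._targets if t.chrom == c]
            for gi in range(len(ctargets) // per):
                group = ctargets[gi * per:(gi + 1) * per]
                name = CANCER_GENES.get((c, gi), f"GENE_{c}_{gi:04d}")
                self._genes.append(
                    GenomicInterval(c, group[0].start - 100, group[-1].end + 100,
                                    label=name)
                )
        half = config.chrom_length // 2
        self._arms = [
            GenomicInterval(c, 0, half, label=f"{c.removeprefix('chr')}p")
            for c in self.chroms
        ] + [
            GenomicInterval(c, half, config.chrom_length,
                            label=f"{c.removeprefix('chr')}q")
            for c in self.chroms
        ]

    def targets(self) -> GenomicIntervalSet:
        return GenomicIntervalSet(self._targets)

    def genes(self) -> GenomicIntervalSet:
        return GenomicIntervalSet(self._genes)

    def arms(self) -> GenomicIntervalSet:
        return GenomicIntervalSet(self._arms)

    def chrom_targets(self, chrom: str) -> list[GenomicInterval]:
        return [t for t in self._targets if t.chrom == chrom]

    def ref_base(self, chrom: str, pos: int) -> str:
        ci = self.chroms.index(chrom)
        return _BASES[((pos * 2654435761 + ci * 97) >> 7) % 4]

    def _ref_base_vec(self, chrom_idx: np.ndarray, pos: np.ndarray) -> np.ndarray:
        h = ((pos.astype(np.int64) * 2654435761 + chrom_idx.astype(np.int64) * 97)
             >> 7) % 4
        return h

    def gene_at(self, chrom: str, pos: int) -> Optional[str]:
        for g in self._genes:
            if g.chrom == chrom and g.start <= pos - 1 < g.end:
                return g.label
        return None

    def random_variant_site(self, rng: np.random.Generator) -> tuple[str, int]:
        """1-based position in the variant zone of a random target."""
        t = self._targets[int(rng.integers(len(self._targets)))]
        return t.chrom, t.start + int(rng.integers(self.VARIANT_ZONE)) + 1

    def random_artifact_sites(
        self, rng: np.random.Generator, n: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """(chrom_idx, pos) arrays in the artifact zones of random targets."""
        idx = rng.integers(len(self._targets), size=n)
        starts = np.array([self._targets[i].start for i in idx])
        chrom_idx = np.array([self.chroms.index(self._targets[i].chrom) for i in idx])
        off = rng.integers(self.VARIANT_ZONE, self.config.target_length, size=n)
        return chrom_idx, starts + off + 1


# ---------------------------------------------------------------------------
# Clone tree


@dataclass
class SimNode:
    """Node of the generating clone tree; ``n_mutations`` mutations arise
    on the edge above this node and are inherited by all its regions."""

    regions: tuple[str, ...]
    n_mutations: int
    children: list["SimNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def nontrivial_clades(self) -> set[frozenset[str]]:
        full = frozenset(self.regions)
        return {
            frozenset(n.regions)
            for n in self.walk()
            if 1 < len(n.regions) < len(full)
        }

    def to_dict(self) -> dict:
        return {
            "regions": list(self.regions),
            "n_mutations": self.n_mutations,
            "children": [c.to_dict() for c in self.children],
        }


def parse_tree_spec(spec: dict) -> SimNode:
    """Explicit clone tree: ``{"n": 8, "children": [{"n": 2, "region":
    "3A"}, {"n": 4, "children": [...]}]}``."""
    if "region" in spec:
        return SimNode(regions=(spec["region"],), n_mutations=int(spec["n"]))
    children = [parse_tree_spec(c) for c in spec["children"]]
    regions = tuple(r for c in children for r in c.regions)
    return SimNode(regions=regions, n_mutations=int(spec["n"]), children=children)


def patient3_example_spec() -> dict:
    """The worked multi-region example: 8 truncal mutations, 4 shared by
    3B and 3C, and 2/1/3 private to 3A/3B/3C."""
    return {
        "n": 8,
        "children": [
            {"n": 2, "region": "3A"},
            {"n": 4, "children": [{"n": 1, "region": "3B"},
                                  {"n": 3, "region": "3C"}]},
        ],
    }


def random_clone_tree(
    rng: np.random.Generator, regions: Sequence[str], config: SimulationConfig
) -> SimNode:
    def build(names: list[str], is_root: bool) -> SimNode:
        if len(names) == 1:
            return SimNode(tuple(names), config.n_private)
        perm = [names[i] for i in rng.permutation(len(names))]
        split = int(rng.integers(1, len(perm)))
        left, right = sorted(perm[:split]), sorted(perm[split:])
        node = SimNode(
            tuple(names),
            config.n_truncal if is_root else config.n_shared,
            [build(left, False), build(right, False)],
        )
        return node

    return build(sorted(regions), True)


# ---------------------------------------------------------------------------
# Truth containers


@dataclass
class RegionTruth:
    germline: set[AlleleKey] = field(default_factory=set)
    somatic: set[AlleleKey] = field(default_factory=set)
    artifacts: set[AlleleKey] = field(default_factory=set)
    artifact_class: dict[AlleleKey, str] = field(default_factory=dict)
    artifact_true_vaf: dict[AlleleKey, float] = field(default_factory=dict)

    @property
    def all_keys(self) -> set[AlleleKey]:
        return self.germline | self.somatic | self.artifacts


@dataclass
class PatientTruth:
    patient_id: str
    tree: SimNode
    regions: dict[str, RegionTruth] = field(default_factory=dict)
    somatic_vaf: dict[AlleleKey, float] = field(default_factory=dict)
    germline_vaf: dict[AlleleKey, float] = field(default_factory=dict)


@dataclass
class TruthBundle:
    patients: dict[str, PatientTruth] = field(default_factory=dict)
    pon: set[AlleleKey] = field(default_factory=set)
    catalog: dict[AlleleKey, float] = field(default_factory=dict)  # pop AF


# ---------------------------------------------------------------------------
# Variant drawing


def _draw_allele(
    genome: GenomeModel,
    rng: np.random.Generator,
    used: set[AlleleKey],
    indel_fraction: float,
) -> AlleleKey:
    """A fresh germline/somatic allele in the variant zone, avoiding any
    site already used for another truth class."""
    while True:
        chrom, pos = genome.random_variant_site(rng)
        if any(k[0] == chrom and k[1] == pos for k in used):
            continue
        ref = genome.ref_base(chrom, pos)
        r = rng.random()
        if r < indel_fraction / 2:  # deletion
            key = (chrom, pos, ref + genome.ref_base(chrom, pos + 1), ref)
        elif r < indel_fraction:  # insertion
            ins = _BASES[int(rng.integers(4))]
            key = (chrom, pos, ref, ref + ins)
        else:
            alt = _BASES[int(rng.integers(4))]
            if alt == ref:
                alt = _BASES[(_BASES.index(ref) + 1 + int(rng.integers(3))) % 4]
            key = (chrom, pos, ref, alt)
        if key[2] == key[3]:
            continue
        used.add(key)
        return key


def draw_artifact_keys(
    genome: GenomeModel,
    rng: np.random.Generator,
    n: int,
    spectrum: dict[str, float],
    pool: Sequence[tuple[AlleleKey, str]] = (),
    pool_fraction: float = 0.0,
) -> tuple[list[AlleleKey], list[str]]:
    """Draw ``n`` distinct artifact SNV keys following the substitution
    spectrum; a configurable fraction comes from a shared recurrent pool
    (the panel-of-normals artifact component)."""
    classes = list(spectrum)
    weights = np.array([spectrum[c] for c in classes], dtype=float)
    weights = weights / weights.sum()

    keys: dict[AlleleKey, str] = {}
    n_pool = int(round(n * pool_fraction)) if pool else 0
    if pool and n_pool:
        idx = rng.choice(len(pool), size=min(n_pool, len(pool)), replace=False)
        for i in sorted(idx):
            key, cls = pool[i]
            keys[key] = cls

    need = n - len(keys)
    while need > 0:
        cls_idx = rng.choice(len(classes), size=need, p=weights)
        pyrimidine = rng.random(need) < 0.5
        chrom_idx, pos = genome.random_artifact_sites(rng, need)
        ref_idx = genome._ref_base_vec(chrom_idx, pos)
        wanted = np.empty(need, dtype="<U1")
        alts = np.empty(need, dtype="<U1")
        for i in range(need):
            cls = classes[cls_idx[i]]
            if pyrimidine[i]:
                wanted[i], alts[i] = cls[0], cls[2]
            else:
                wanted[i], alts[i] = _COMPLEMENT[cls[0]], _COMPLEMENT[cls[2]]
        refs = np.array(list(_BASES))[ref_idx]
        ok = refs == wanted
        for i in np.nonzero(ok)[0]:
            chrom = genome.chroms[int(chrom_idx[i])]
            key = (chrom, int(pos[i]), str(refs[i]), str(alts[i]))
            if key not in keys:
                keys[key] = classes[cls_idx[i]]
        need = n - len(keys)
    ordered = list(keys)[:n]
    return ordered, [keys[k] for k in ordered]


def _clip(x: float, low: float, high: Optional[float] = None) -> float:
    if high is not None:
        x = min(x, high)
    return max(x, low)


def _true_metrics(rng: np.random.Generator) -> dict:
    return {
        "mapping_quality": _clip(rng.normal(58, 3), 1),
        "mean_mismatches": _clip(rng.normal(1.2, 0.4), 0),
        "mean_pos_in_read": _clip(rng.normal(28, 5), 1),
        "ms_length": float(rng.poisson(0.5)),
        "tlod": _clip(rng.normal(60, 20), 0),
        "fs_phred": float(rng.exponential(2.0)),
    }


def _artifact_metrics(rng: np.random.Generator) -> dict:
    return {
        "mapping_quality": _clip(rng.normal(50, 8), 1),
        "mean_mismatches": _clip(rng.normal(2.8, 0.8), 0),
        "mean_pos_in_read": _clip(rng.normal(12, 6), 1),
        "ms_length": float(rng.poisson(1.5)),
        "tlod": _clip(rng.normal(6, 4), 0),
        "fs_phred": _clip(rng.normal(35, 10), 0),
    }


def _make_call(
    key: AlleleKey,
    rng: np.random.Generator,
    genome: GenomeModel,
    true_vaf: float,
    mean_coverage: float,
    metrics: dict,
    quality: float,
    one_sided_strand: bool,
    pop_af: Optional[float] = None,
    is_somatic: bool = False,
    force_alt: bool = False,
) -> Optional[VariantCall]:
    chrom, pos, ref, alt = key
    depth = max(1, int(rng.poisson(mean_coverage)))
    alt_n = int(rng.binomial(depth, min(true_vaf, 1.0)))
    if force_alt:
        alt_n = max(1, alt_n)
    if alt_n == 0:
        return None  # allelic dropout: the callers never see it
    if one_sided_strand:
        fwd = alt_n if rng.random() < 0.5 else 0
    else:
        fwd = int(rng.binomial(alt_n, 0.5))
    gene = genome.gene_at(chrom, pos)
    is_cancer_gene = gene in set(CANCER_GENES.values())
    return VariantCall(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        vaf=alt_n / depth,
        depth=depth,
        alt_forward=fwd,
        alt_reverse=alt_n - fwd,
        ensemble_quality=round(quality, 2),
        pop_af=pop_af,
        gene=gene,
        is_cgc_tier1=is_cancer_gene,
        in_cosmic=is_somatic and is_cancer_gene,
        in_clinvar=False,
        is_hotspot_gene=gene in ("PIK3CA", "TP53", "GATA3"),
        effect_class=("non_silent" if is_somatic and rng.random() < 0.7 else "silent")
        if is_somatic
        else "unknown",
        **metrics,
    )


# ---------------------------------------------------------------------------
# Copy number


def simulate_copy_number(
    config: SimulationConfig,
    genome: GenomeModel,
    rng: np.random.Generator,
) -> tuple[list[CopyNumberBin], list[CopyNumberSegment]]:
    """Realize the configured CNA event list as bins + segments for one
    region.  Bins are one per target at the segment log2 plus Gaussian
    noise; segment statistics (CI, biweight midvariance) are computed from
    their bins.  Overlapping events on one chromosome are an error."""
    arm_by_label = {a.label: a for a in genome.arms()}
    events_by_chrom: dict[str, list[tuple[int, int, float, Optional[float]]]] = {
        c: [] for c in genome.chroms
    }
    for ev in config.cna_events:
        baf = ev.get("baf")
        if "arm" in ev:
            arm = arm_by_label[ev["arm"]]
            ctargets = [
                t for t in genome.chrom_targets(arm.chrom)
                if t.start >= arm.start and t.end <= arm.end
            ]
            n_cov = max(1, int(round(len(ctargets) * float(ev.get("fraction", 1.0)))))
            span = (ctargets[0].start, ctargets[n_cov - 1].end)
            events_by_chrom[arm.chrom].append(
                (span[0], span[1], float(ev["log2"]), baf)
            )
        else:
            ctargets = genome.chrom_targets(ev["chrom"])
            lo, hi = int(ev["start_target"]), int(ev["end_target"])
            events_by_chrom[ev["chrom"]].append(
                (ctargets[lo].start, ctargets[hi - 1].end, float(ev["log2"]), baf)
            )

    bins: list[CopyNumberBin] = []
    segments: list[CopyNumberSegment] = []
    for chrom in genome.chroms:
        ctargets = genome.chrom_targets(chrom)
        events = sorted(events_by_chrom[chrom])
        for i in range(1, len(events)):
            if events[i][0] < events[i - 1][1]:
                raise PmlseqError(
                    f"overlapping CNA events configured on {chrom}"
                )
        covered = (ctargets[0].start, ctargets[-1].end)
        # partition the covered span at event boundaries
        pieces: list[tuple[int, int, float, Optional[float]]] = []
        cursor = covered[0]
        for start, end, log2, baf in events:
            if cursor < start:
                pieces.append((cursor, start, 0.0, None))
            pieces.append((start, end, log2, baf))
            cursor = end
        if cursor < covered[1]:
            pieces.append((cursor, covered[1], 0.0, None))
        for start, end, log2, baf in pieces:
            seg_targets = [t for t in ctargets if t.start >= start and t.end <= end]
            if not seg_targets:
                continue
            values = rng.normal(log2, config.bin_noise_sd, size=len(seg_targets))
            for t, v in zip(seg_targets, values):
                bins.append(CopyNumberBin(chrom, t.start, t.end, float(v)))
            mean = float(np.mean(values))
            sem = float(np.std(values, ddof=1) / np.sqrt(len(values))) if len(values) > 1 else 0.0
            if baf is None:
                seg_baf = _clip(0.5 + rng.normal(0, 0.02), 0.0, 1.0)
            else:
                seg_baf = _clip(baf + rng.normal(0, 0.01), 0.0, 1.0)
            segments.append(
                CopyNumberSegment(
                    chrom=chrom,
                    start=start,
                    end=end,
                    log2=mean,
                    n_probes=len(seg_targets),
                    ci_low=mean - 1.96 * sem,
                    ci_high=mean + 1.96 * sem,
                    bivar=biweight_midvariance(values),
                    baf=seg_baf,
                )
            )
    return bins, segments


# ---------------------------------------------------------------------------
# Patient / cohort simulation


def _build_catalog(
    config: SimulationConfig, genome: GenomeModel, rng: np.random.Generator
) -> dict[AlleleKey, float]:
    used: set[AlleleKey] = set()
    catalog: dict[AlleleKey, float] = {}
    for _ in range(config.n_population_sites):
        key = _draw_allele(genome, rng, used, config.indel_fraction)
        if rng.random() < config.population_common_fraction:
            af = float(10 ** rng.uniform(-2, -0.3))  # common: 1e-2 .. 0.5
        else:
            af = float(10 ** rng.uniform(-5, -3.2))  # rare: below the MAF cut
        catalog[key] = af
    return catalog


def simulate_patient(
    config: SimulationConfig,
    patient_index: int,
    genome: GenomeModel,
    catalog: dict[AlleleKey, float],
    artifact_pool: list[tuple[AlleleKey, str]],
    somatic_used: set[AlleleKey],
) -> tuple[Patient, PatientTruth]:
    """Simulate one patient: clone tree, germline, per-region caller call
    sets, artifacts, copy number and count tables.

    ``somatic_used`` accumulates somatic keys across patients so true
    somatic mutations are never shared between patients (the cross-patient
    recurrence filter would otherwise remove planted truth).
    """
    if config.regions_per_patient < 1:
        raise PmlseqError("regions_per_patient must be >= 1")
    prng = np.random.default_rng([config.seed, 1000 + patient_index])
    pid = f"P{patient_index + 1}"
    if config.tree_spec is not None:
        tree = parse_tree_spec(config.tree_spec)
        region_ids = list(tree.regions)
    else:
        region_ids = [f"{pid}{chr(ord('A') + i)}"
                      for i in range(config.regions_per_patient)]
        if len(region_ids) == 1:
            tree = SimNode(tuple(region_ids), config.n_truncal)
        else:
            tree = random_clone_tree(prng, region_ids, config)

    truth = PatientTruth(patient_id=pid, tree=tree)

    # germline: sampled from the shared population catalog
    catalog_keys = list(catalog)
    germ_idx = prng.choice(len(catalog_keys), size=config.n_germline, replace=False)
    germline: dict[AlleleKey, float] = {}
    for i in sorted(germ_idx):
        key = catalog_keys[i]
        hom = prng.random() < config.germline_hom_fraction
        germline[key] = 1.0 if hom else 0.5
    truth.germline_vaf = dict(germline)

    # somatic mutations on the clone tree
    used = set(catalog) | set(somatic_used) | set(germline)
    node_mutations: list[tuple[SimNode, AlleleKey]] = []
    for node in tree.walk():
        for _ in range(node.n_mutations):
            key = _draw_allele(genome, prng, used, config.indel_fraction)
            somatic_used.add(key)
            vaf = float(prng.uniform(config.somatic_vaf_low, config.somatic_vaf_high))
            truth.somatic_vaf[key] = vaf
            node_mutations.append((node, key))
    somatic_by_region: dict[str, list[AlleleKey]] = {r: [] for r in region_ids}
    for node, key in node_mutations:
        for r in node.regions:
            somatic_by_region[r].append(key)

    regions: list[RegionData] = []
    for r_index, rid in enumerate(region_ids):
        rrng = np.random.default_rng(
            [config.seed, 1000 + patient_index, r_index]
        )
        rtruth = RegionTruth()
        caller1, caller2 = config.caller_labels
        calls_by_caller: dict[str, list[VariantCall]] = {caller1: [], caller2: []}

        def emit(call: Optional[VariantCall], concordance: float) -> bool:
            """Bernoulli presence per caller; returns True if any caller
            reports the variant."""
            if call is None:
                return False
            seen = False
            for label in (caller1, caller2):
                if rrng.random() < concordance:
                    calls_by_caller[label].append(
                        call.with_(callers=frozenset({label}))
                    )
                    seen = True
            return seen

        for key, vaf in germline.items():
            call = _make_call(
                key, rrng, genome, vaf, config.mean_coverage,
                _true_metrics(rrng),
                _clip(rrng.normal(config.quality_true_mean, config.quality_true_sd), 1),
                one_sided_strand=False,
                pop_af=catalog[key],
            )
            emit(call, config.concordance_true)
            rtruth.germline.add(key)

        for key in somatic_by_region[rid]:
            call = _make_call(
                key, rrng, genome, truth.somatic_vaf[key], config.mean_coverage,
                _true_metrics(rrng),
                _clip(rrng.normal(config.quality_true_mean, config.quality_true_sd), 1),
                one_sided_strand=False,
                is_somatic=True,
            )
            emit(call, config.concordance_true)
            rtruth.somatic.add(key)

        art_keys, art_classes = draw_artifact_keys(
            genome, rrng, config.n_artifacts, config.spectrum,
            pool=artifact_pool, pool_fraction=config.artifact_pool_fraction,
        )
        art_vafs = rrng.beta(
            config.artifact_vaf_alpha, config.artifact_vaf_beta,
            size=len(art_keys),
        )
        art_presence = rrng.random((len(art_keys), 2)) < config.concordance_artifact
        for i, key in enumerate(art_keys):
            rtruth.artifacts.add(key)
            rtruth.artifact_class[key] = art_classes[i]
            rtruth.artifact_true_vaf[key] = float(art_vafs[i])
            if not art_presence[i].any():
                continue
            call = _make_call(
                key, rrng, genome, float(art_vafs[i]), config.mean_coverage,
                _artifact_metrics(rrng),
                _clip(rrng.normal(config.quality_artifact_mean,
                                  config.quality_artifact_sd), 1),
                one_sided_strand=True,
                force_alt=True,
            )
            if call is None:
                continue
            for j, label in enumerate((caller1, caller2)):
                if art_presence[i, j]:
                    calls_by_caller[label].append(
                        call.with_(callers=frozenset({label}))
                    )

        bins, segments = simulate_copy_number(config, genome, rrng)

        # joint re-extraction counts at every germline/somatic site
        counts: dict[AlleleKey, tuple[int, int]] = {}
        union = sorted(set(germline) | set(truth.somatic_vaf))
        present = set(germline) | set(somatic_by_region[rid])
        for key in union:
            depth = max(1, int(rrng.poisson(config.counts_coverage)))
            vaf = (
                germline.get(key, truth.somatic_vaf.get(key, 0.0))
                if key in present
                else config.count_error_rate
            )
            counts[key] = (int(rrng.binomial(depth, min(vaf, 1.0))), depth)

        for label in calls_by_caller:
            calls_by_caller[label].sort(key=lambda v: v.key)
        regions.append(
            RegionData(
                region_id=rid,
                caller_variants=calls_by_caller,
                bins=bins,
                segments=segments,
                counts=counts,
            )
        )
        truth.regions[rid] = rtruth

    return Patient(pid, regions), truth


def simulate_cohort(config: SimulationConfig) -> tuple[PatientCohort, TruthBundle]:
    """Simulate the full cohort plus its truth bundle (population catalog,
    panel of normals, per-patient clone trees and truth classes)."""
    genome = GenomeModel(config)
    grng = np.random.default_rng([config.seed, 7])
    catalog = _build_catalog(config, genome, grng)

    pool_keys, pool_classes = draw_artifact_keys(
        genome, grng, config.artifact_pool_size, config.spectrum
    )
    artifact_pool = list(zip(pool_keys, pool_classes))

    catalog_keys = list(catalog)
    n_pon = int(round(len(catalog_keys) * config.pon_catalog_fraction))
    pon_idx = grng.choice(len(catalog_keys), size=n_pon, replace=False)
    pon = {catalog_keys[i] for i in sorted(pon_idx)} | set(pool_keys)

    truth = TruthBundle(pon=pon, catalog=catalog)
    patients = []
    somatic_used: set[AlleleKey] = set()
    for p in range(config.n_patients):
        patient, ptruth = simulate_patient(
            config, p, genome, catalog, artifact_pool, somatic_used
        )
        patients.append(patient)
        truth.patients[patient.patient_id] = ptruth
    return PatientCohort(patients), truth


# ---------------------------------------------------------------------------
# File emission


def emit_caller_vcfs(
    region: RegionData, config: SimulationConfig, genome: GenomeModel, outdir
) -> list[Path]:
    """Write the region's two caller call sets as VCFs.  Caller-specific
    field masking mirrors real tools: only the first caller reports read
    position / mismatch / microsatellite metrics, only the second reports
    the tumor log-odds."""
    outdir = Path(outdir)
    caller1, caller2 = config.caller_labels
    paths = []
    mask = {
        caller1: ("tlod",),
        caller2: ("mean_pos_in_read", "mean_mismatches", "ms_length"),
    }
    for label in (caller1, caller2):
        masked = [
            v.with_(**{m: None for m in mask[label]})
            for v in region.caller_variants[label]
        ]
        path = outdir / f"{region.region_id}.{label}.vcf"
        write_variants(path, masked, contigs=genome.contigs)
        paths.append(path)
    return paths


def write_cohort(
    cohort: PatientCohort,
    truth: TruthBundle,
    config: SimulationConfig,
    outdir,
) -> None:
    """Write the whole simulated cohort as plain-text files: per-region
    caller VCFs, .cnr/.cns, count tables; cohort-level BEDs, PoN VCF,
    truth TSVs, clone trees JSON and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = GenomeModel(config)
    write_bed(outdir / "targets.bed", genome.targets())
    write_bed(outdir / "genes.bed", genome.genes())
    write_bed(outdir / "arms.bed", genome.arms())
    config.to_yaml(outdir / "sim_config.yaml")

    pon_calls = [
        VariantCall(chrom=c, pos=p, ref=r, alt=a, pop_af=truth.catalog.get((c, p, r, a)))
        for (c, p, r, a) in sorted(truth.pon)
    ]
    write_variants(outdir / "pon.vcf", pon_calls, contigs=genome.contigs)

    manifest: dict = {"caller_labels": list(config.caller_labels), "patients": []}
    truth_rows = []
    trees = {}
    for patient in cohort:
        ptruth = truth.patients[patient.patient_id]
        trees[patient.patient_id] = ptruth.tree.to_dict()
        pentry = {"id": patient.patient_id, "regions": []}
        for region in patient.regions:
            emit_caller_vcfs(region, config, genome, outdir)
            write_bins(outdir / f"{region.region_id}.cnr", region.bins)
            write_segments(outdir / f"{region.region_id}.cns", region.segments)
            write_counts(outdir / f"{region.region_id}.counts.tsv", region.counts)
            pentry["regions"].append(region.region_id)
            rtruth = ptruth.regions[region.region_id]
            for cls_name, keys in (
                ("germline", rtruth.germline),
                ("somatic", rtruth.somatic),
                ("artifact", rtruth.artifacts),
            ):
                for key in sorted(keys):
                    truth_rows.append(
                        (patient.patient_id, region.region_id, cls_name, *key)
                    )
        manifest["patients"].append(pentry)

    import pandas as pd

    pd.DataFrame(
        truth_rows,
        columns=["patient", "region", "class", "chrom", "pos", "ref", "alt"],
    ).to_csv(outdir / "truth_variants.tsv", sep="\t", index=False)
    with open(outdir / "clone_trees.json", "w") as fh:
        json.dump(trees, fh, indent=1, sort_keys=True)
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def load_cohort(outdir) -> PatientCohort:
    """Reload a written cohort (caller VCFs, bins/segments, counts) into a
    PatientCohort via the manifest."""
    from .formats_io import read_bins, read_counts, read_segments, read_variants

    outdir = Path(outdir)
    with open(outdir / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    caller1, caller2 = manifest["caller_labels"]
    patients = []
    for pentry in manifest["patients"]:
        regions = []
        for rid in pentry["regions"]:
            caller_variants = {
                label: read_variants(outdir / f"{rid}.{label}.vcf", label)
                for label in (caller1, caller2)
            }
            regions.append(
                RegionData(
                    region_id=rid,
                    caller_variants=caller_variants,
                    bins=read_bins(outdir / f"{rid}.cnr"),
                    segments=read_segments(outdir / f"{rid}.cns"),
                    counts=read_counts(outdir / f"{rid}.counts.tsv"),
                )
            )
        patients.append(Patient(pentry["id"], regions))
    return PatientCohort(patients)
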