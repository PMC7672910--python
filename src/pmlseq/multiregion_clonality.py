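"""Multi-region mutation classification and clone-tree construction.

For every candidate mutation found in any region of a patient, read counts
at that position are re-examined in *all* regions, and each (mutation,
region) cell is classified present or absent under a two-hypothesis
Bayesian read-count model:

* absent: alt reads arise from sequencing/damage error alone,
  ``L0 = Binomial(alt; depth, e)`` with error rate ``e`` (default 0.02);
* present: the allele fraction is unknown, uniform on [0, 1], giving the
  marginal likelihood ``L1 = 1/(depth + 1)``.

The posterior of presence is ``prior * L1 / (prior * L1 + (1-prior) * L0)``.
This is a transparent simplification of published multi-region callers
(which optimize a richer model over all regions jointly): it preserves the
testable contract — a posterior presence matrix and a region tree.

The binarized matrix is then summarized as a clone tree by parsimony: when
the mutation presence patterns admit a perfect phylogeny (every pattern
arises once on the tree, no reversals), that tree is returned with edge
mutation counts; otherwise regions are agglomerated greedily to maximize
the number of compatible characters, and the homoplasy count is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .cna_profile import call_loh
from .model import AlleleKey, Patient, PmlseqError, RegionData

PRESENT = "present"
ABSENT = "absent"
UNKNOWN = "unknown"


def propagate_germline_exclusion(
    patient: Patient, vaf_threshold: float = 0.9
) -> Patient:
    """Cross-region germline propagation: any allele found at VAF above
    the threshold in a non-LOH segment of *one* region is excluded from
    every region of the patient.

    The comparison is strict (> threshold).  LOH status comes from the
    region's own segments.  Idempotent: re-applying changes nothing.
    """
    germline_keys: set[AlleleKey] = set()
    for region in patient.regions:
        loh_segments = [
            c.segment for c in call_loh(region.segments) if c.is_loh
        ]
        for v in region.variants:
            if v.vaf is None or not v.vaf > vaf_threshold:
                continue
            if any(s.contains(v.chrom, v.pos - 1) for s in loh_segments):
                continue
            germline_keys.add(v.key)
    new_regions = [
        RegionData(
            region_id=r.region_id,
            variants=[v for v in r.variants if v.key not in germline_keys],
            caller_variants=r.caller_variants,
            bins=r.bins,
            segments=r.segments,
            counts=r.counts,
        )
        for r in patient.regions
    ]
    return Patient(patient.patient_id, new_regions)


def presence_posterior(
    alt: int, depth: int, e: float = 0.02, prior: float = 0.5
) -> float:
    """Posterior probability that a mutation is present given ``alt``
    alt-supporting reads out of ``depth``.

    With no reads (depth 0) both likelihoods are 1 and the posterior
    equals the prior.
    """
    if depth < 0:
        raise PmlseqError(f"negative depth: {depth}")
    if not 0 <= alt <= depth:
        raise PmlseqError(f"alt={alt} outside [0, depth={depth}]")
    if not 0.0 < e < 0.5:
        raise PmlseqError(f"error rate must lie in (0, 0.5), got {e}")
    if not 0.0 <= prior <= 1.0:
        raise PmlseqError(f"prior must lie in [0, 1], got {prior}")
    l1 = 1.0 / (depth + 1)
    l0 = float(stats.binom.pmf(alt, depth, e))
    denom = prior * l1 + (1.0 - prior) * l0
    if denom == 0.0:  # numerically impossible alt under both models
        return 1.0 if alt > 0 else prior
    return prior * l1 / denom


@dataclass
class PresenceMatrix:
    """Mutations x regions posterior-presence matrix for one patient."""

    patient_id: str
    mutations: list[AlleleKey]
    regions: list[str]
    alt: np.ndarray  # int, -1 where counts are missing
    depth: np.ndarray
    posterior: np.ndarray  # float, nan where unknown
    classification: np.ndarray  # str objects: present/absent/unknown

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.mutations), len(self.regions))

    def present_set(self, i: int) -> frozenset[str]:
        return frozenset(
            r
            for j, r in enumerate(self.regions)
            if self.classification[i, j] == PRESENT
        )

    def fully_known(self, i: int) -> bool:
        return all(
            self.classification[i, j] != UNKNOWN for j in range(len(self.regions))
        )

    def to_frame(self):
        import pandas as pd

        rows = []
        for i, key in enumerate(self.mutations):
            for j, region in enumerate(self.regions):
                rows.append(
                    {
                        "chrom": key[0],
                        "pos": key[1],
                        "ref": key[2],
                        "alt_allele": key[3],
                        "region": region,
                        "alt_count": int(self.alt[i, j]),
                        "depth": int(self.depth[i, j]),
                        "posterior": float(self.posterior[i, j]),
                        "classification": self.classification[i, j],
                    }
                )
        return pd.DataFrame(rows)


def build_presence_matrix(
    patient: Patient,
    min_depth: int = 5,
    decision_threshold: float = 0.5,
    e: float = 0.02,
    prior: float = 0.5,
) -> PresenceMatrix:
    """Classify every candidate mutation of the patient in every region.

    Candidates are the union of the regions' variant lists.  Per-region
    (alt, depth) counts come from ``region.counts`` (joint re-extraction);
    when absent they are reconstructed from the region's own call
    (``vaf * depth``).  A cell with missing counts or depth below
    ``min_depth`` is ``unknown``.
    """
    keys = sorted({v.key for r in patient.regions for v in r.variants})
    regions = patient.region_ids
    n, m = len(keys), len(regions)
    alt = np.full((n, m), -1, dtype=int)
    depth = np.full((n, m), -1, dtype=int)
    post = np.full((n, m), np.nan)
    cls = np.full((n, m), UNKNOWN, dtype=object)

    for j, region in enumerate(patient.regions):
        counts = dict(region.counts) if region.counts else {}
        for v in region.variants:
            if v.key not in counts and v.depth is not None and v.vaf is not None:
                counts[v.key] = (int(round(v.vaf * v.depth)), v.depth)
        for i, key in enumerate(keys):
            if key not in counts:
                continue
            a, d = counts[key]
            alt[i, j], depth[i, j] = a, d
            if d < min_depth:
                continue
            p = presence_posterior(a, d, e=e, prior=prior)
            post[i, j] = p
            cls[i, j] = PRESENT if p >= decision_threshold else ABSENT
    return PresenceMatrix(
        patient_id=patient.patient_id,
        mutations=keys,
        regions=regions,
        alt=alt,
        depth=depth,
        posterior=post,
        classification=cls,
    )


@dataclass
class CloneNode:
    regions: frozenset[str]
    mutations: list[AlleleKey] = field(default_factory=list)
    children: list["CloneNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def newick(self) -> str:
        length = len(self.mutations)
        if self.is_leaf:
            return f"{next(iter(self.regions))}:{length}"
        inner = ",".join(c.newick() for c in sorted(
            self.children, key=lambda c: sorted(c.regions)
        ))
        return f"({inner}):{length}"


@dataclass
class CloneTree:
    root: CloneNode
    regions: list[str]
    homoplasy_count: int = 0
    conflict_free: bool = True
    unplaced: list[AlleleKey] = field(default_factory=list)

    def clades(self, nontrivial: bool = True) -> set[frozenset[str]]:
        """Region sets of the tree's nodes; with ``nontrivial`` only those
        strictly between a single leaf and the full region set."""
        out: set[frozenset[str]] = set()

        def walk(node: CloneNode) -> None:
            out.add(node.regions)
            for c in node.children:
                walk(c)

        walk(self.root)
        if nontrivial:
            full = frozenset(self.regions)
            out = {c for c in out if 1 < len(c) < len(full)}
        return out

    def newick(self) -> str:
        return self.root.newick() + ";"

    def edge_counts(self) -> dict[frozenset[str], int]:
        counts: dict[frozenset[str], int] = {}

        def walk(node: CloneNode) -> None:
            counts[node.regions] = len(node.mutations)
            for c in node.children:
                walk(c)

        walk(self.root)
        return counts


def _compatible(a: frozenset, b: frozenset) -> bool:
    return a <= b or b <= a or not (a & b)


def _build_from_clades(
    clade_sets: set[frozenset[str]],
    regions: Sequence[str],
) -> CloneNode:
    full = frozenset(regions)
    sets = set(clade_sets) | {full} | {frozenset({r}) for r in regions}
    ordered = sorted(sets, key=lambda s: (-len(s), sorted(s)))
    nodes = {s: CloneNode(regions=s) for s in ordered}
    for s in ordered:
        if s == full:
            continue
        parent = min(
            (t for t in ordered if len(t) > len(s) and s < t),
            key=len,
        )
        nodes[parent].children.append(nodes[s])
    for node in nodes.values():
        node.children.sort(key=lambda c: sorted(c.regions))
    return nodes[full]


def infer_tree(matrix: PresenceMatrix) -> CloneTree:
    """Summarize the binarized presence matrix as a rooted region tree.

    Characters are the presence patterns of fully-known mutations.  If
    every pair of patterns is nested or disjoint (perfect phylogeny), the
    nested-set hierarchy is the tree.  Otherwise regions are merged
    greedily — the pair of clusters sharing the most mutations first, ties
    broken lexicographically — and mutations whose pattern is not a clade
    of the result are counted as homoplasies.  Mutations with unknown
    cells are placed on the smallest containing clade but define no clade
    themselves; mutations absent everywhere are reported unplaced.
    """
    regions = list(matrix.regions)
    full = frozenset(regions)
    if len(regions) < 2:
        root = CloneNode(regions=full, mutations=list(matrix.mutations))
        return CloneTree(root=root, regions=regions)

    characters: list[tuple[AlleleKey, frozenset[str], bool]] = []
    for i, key in enumerate(matrix.mutations):
        pset = matrix.present_set(i)
        characters.append((key, pset, matrix.fully_known(i)))

    known_sets = [p for _, p, known in characters if known and p]
    distinct = set(known_sets)
    conflict_free = all(
        _compatible(a, b) for a in distinct for b in distinct
    )

    if conflict_free:
        root = _build_from_clades(distinct, regions)
    else:
        root = _greedy_agglomerate(known_sets, regions)

    clade_nodes: dict[frozenset[str], CloneNode] = {}

    def index(node: CloneNode) -> None:
        clade_nodes[node.regions] = node
        for c in node.children:
            index(c)

    index(root)
    ordered_clades = sorted(clade_nodes, key=len)

    homoplasy = 0
    unplaced: list[AlleleKey] = []
    for key, pset, known in characters:
        if not pset:
            unplaced.append(key)
            continue
        host = next(c for c in ordered_clades if pset <= c)
        clade_nodes[host].mutations.append(key)
        if known and host != pset:
            homoplasy += 1
    return CloneTree(
        root=root,
        regions=regions,
        homoplasy_count=homoplasy,
        conflict_free=conflict_free,
        unplaced=unplaced,
    )


def _greedy_agglomerate(
    present_sets: Sequence[frozenset[str]], regions: Sequence[str]
) -> CloneNode:
    clusters: list[CloneNode] = [
        CloneNode(regions=frozenset({r})) for r in sorted(regions)
    ]

    def shared(a: CloneNode, b: CloneNode) -> int:
        union = a.regions | b.regions
        return sum(1 for p in present_sets if union <= p)

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                score = shared(clusters[i], clusters[j])
                tie = (sorted(clusters[i].regions), sorted(clusters[j].regions))
                cand = (-score, tie, i, j)
                if best is None or cand < best:
                    best = cand
        _, _, i, j = best
        merged = CloneNode(
            regions=clusters[i].regions | clusters[j].regions,
            children=[clusters[i], clusters[j]],
        )
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    root = clusters[0]
    root.children.sort(key=lambda c: sorted(c.regions))
    return root
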