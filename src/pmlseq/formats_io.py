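"""Readers and writers for every external representation.

VCF 4.2 (via pysam) for variants, CNVkit-style tab-delimited ``.cnr`` /
``.cns`` for copy-number bins and segments, BED3+label for targets /
genes / chromosome arms, and TSV for count tables and reports.

VCF coordinates are 1-based (their native convention); bins, segments and
BED are 0-based half-open.  Conversion happens only here, at the I/O
boundary.  Metric keys in VCF INFO are configurable through a field map
whose defaults follow VarDict / Mutect2 conventions (``PMEAN``, ``NM``,
``MSILEN``, ``TLOD``, ``FS``, ...); the ensemble quality score travels in
the QUAL column.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
import pysam

from .model import (
    AlleleKey,
    CopyNumberBin,
    CopyNumberSegment,
    GenomicInterval,
    GenomicIntervalSet,
    PmlseqError,
    VariantCall,
    left_normalize,
)

PathLike = Union[str, Path]


class VariantFileError(PmlseqError):
    """Unreadable or malformed variant file."""


class TableFormatError(PmlseqError):
    """Missing column or invalid row in a tab-delimited table."""


# metric / annotation  ->  INFO key.  QUAL carries ensemble_quality.
DEFAULT_FIELD_MAP: dict[str, str] = {
    "vaf": "AF",
    "depth": "DP",
    "alt_forward": "SAF",
    "alt_reverse": "SAR",
    "mapping_quality": "MQ",
    "mean_mismatches": "NM",
    "mean_pos_in_read": "PMEAN",
    "ms_length": "MSILEN",
    "tlod": "TLOD",
    "fs_phred": "FS",
    "pop_af": "POP_AF",
    "gene": "GENE",
    "is_cgc_tier1": "CGC_T1",
    "in_cosmic": "COSMIC",
    "in_clinvar": "CLINVAR",
    "is_hotspot_gene": "HOTSPOT",
    "effect_class": "EFF",
}

_INT_FIELDS = {"depth", "alt_forward", "alt_reverse"}
_FLAG_FIELDS = {"is_cgc_tier1", "in_cosmic", "in_clinvar", "is_hotspot_gene"}
_STR_FIELDS = {"gene", "effect_class"}

_INFO_DEFS = {
    "AF": ("A", "Float", "Variant allelic fraction"),
    "DP": ("1", "Integer", "Total read depth at site"),
    "SAF": ("A", "Integer", "Alt-supporting reads on forward strand"),
    "SAR": ("A", "Integer", "Alt-supporting reads on reverse strand"),
    "MQ": ("1", "Float", "Mean mapping quality"),
    "NM": ("1", "Float", "Mean number of read mismatches"),
    "PMEAN": ("1", "Float", "Mean position of allele in read"),
    "MSILEN": ("1", "Float", "Microsatellite run length"),
    "TLOD": ("A", "Float", "Tumor log-odds"),
    "FS": ("1", "Float", "Fisher strand bias, Phred-scaled"),
    "POP_AF": ("A", "Float", "Max population allele frequency"),
    "GENE": ("1", "String", "Gene symbol"),
    "CGC_T1": ("0", "Flag", "Tier 1 cancer gene"),
    "COSMIC": ("0", "Flag", "Present in COSMIC"),
    "CLINVAR": ("0", "Flag", "Present in ClinVar"),
    "HOTSPOT": ("0", "Flag", "Hotspot gene"),
    "EFF": ("1", "String", "Predicted effect class"),
}


def _per_allele(value, allele_index: int):
    if isinstance(value, (tuple, list)):
        if allele_index < len(value):
            return value[allele_index]
        return value[0] if value else None
    return value


def read_variants(
    path: PathLike,
    caller_label: str,
    field_map: Optional[Mapping[str, str]] = None,
    get_base: Optional[Callable[[str, int], str]] = None,
) -> list[VariantCall]:
    """Read a VCF into :class:`VariantCall` records.

    One record per ALT allele (multiallelic sites are split).  Metrics
    absent from a record stay ``None``.  ``get_base(chrom, pos)`` enables
    reference-aware left-normalization of indels.
    """
    fmap = dict(DEFAULT_FIELD_MAP)
    if field_map:
        fmap.update(field_map)
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VariantFileError(f"cannot read VCF {path}: {exc}") from exc
    out: list[VariantCall] = []
    record_no = 0
    try:
        with vf:
            for rec in vf:
                record_no += 1
                try:
                    out.extend(_parse_record(rec, caller_label, fmap, get_base))
                except (ValueError, KeyError, TypeError) as exc:
                    raise VariantFileError(
                        f"{path}: malformed record {record_no} "
                        f"({rec.chrom}:{rec.pos}): {exc}"
                    ) from exc
    except VariantFileError:
        raise
    except (OSError, ValueError) as exc:  # pragma: no cover - parser-level
        raise VariantFileError(
            f"{path}: parse error after record {record_no}: {exc}"
        ) from exc
    return out


def _parse_record(rec, caller_label, fmap, get_base) -> list[VariantCall]:
    calls = []
    alts = rec.alts or ()
    for i, alt in enumerate(alts):
        if alt is None or alt in (".", "*", "<NON_REF>"):
            continue
        fields: dict = {
            "callers": frozenset({caller_label}),
            "ensemble_quality": rec.qual if rec.qual is not None else None,
        }
        for name, key in fmap.items():
            if key not in rec.info:
                if name in _FLAG_FIELDS:
                    fields[name] = False
                continue
            raw = _per_allele(rec.info.get(key), i)
            if name in _FLAG_FIELDS:
                fields[name] = bool(raw)
            elif name in _STR_FIELDS:
                fields[name] = None if raw in (None, ".") else str(raw)
            elif raw is None:
                continue
            elif name in _INT_FIELDS:
                fields[name] = int(raw)
            else:
                fields[name] = float(raw)
        pos, ref, nalt = rec.pos, rec.ref.upper(), alt.upper()
        lookup = (lambda p, c=rec.chrom: get_base(c, p)) if get_base else None
        pos, ref, nalt = left_normalize(pos, ref, nalt, lookup)
        calls.append(VariantCall(chrom=rec.chrom, pos=pos, ref=ref, alt=nalt, **fields))
    return calls


def write_variants(
    path: PathLike,
    variants: Sequence[VariantCall],
    contigs: Optional[Mapping[str, int]] = None,
    field_map: Optional[Mapping[str, str]] = None,
) -> None:
    """Write VariantCall records as an uncompressed VCF 4.2 file."""
    fmap = dict(DEFAULT_FIELD_MAP)
    if field_map:
        fmap.update(field_map)
    header = pysam.VariantHeader()
    if contigs is None:
        contigs = {}
        for v in variants:
            contigs[v.chrom] = max(contigs.get(v.chrom, 0), v.pos + len(v.ref) + 1000)
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    for name, key in fmap.items():
        number, vtype, desc = _INFO_DEFS.get(key, ("1", "Float", name))
        header.info.add(key, number, vtype, desc)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in variants:
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt)
            )
            if v.ensemble_quality is not None:
                rec.qual = v.ensemble_quality
            for name, key in fmap.items():
                val = getattr(v, name)
                if name in _FLAG_FIELDS:
                    if val:
                        rec.info[key] = True
                    continue
                if val is None:
                    continue
                number = _INFO_DEFS.get(key, ("1",))[0]
                rec.info[key] = (val,) if number == "A" else val
            out.write(rec)


# ---------------------------------------------------------------------------
# CNVkit-style tables

_BIN_COLUMNS = ["chromosome", "start", "end", "log2"]
_SEG_COLUMNS = ["chromosome", "start", "end", "log2", "probes"]
_SEG_OPTIONAL = ["ci_lo", "ci_hi", "bivar", "baf"]


def _read_table(path: PathLike, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except OSError as exc:
        raise TableFormatError(f"cannot read {path}: {exc}") from exc
    df = df.rename(columns={"chrom": "chromosome"})
    for col in required:
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing required column {col!r}")
    return df


def read_bins(path: PathLike) -> list[CopyNumberBin]:
    df = _read_table(path, _BIN_COLUMNS)
    bins = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            bins.append(
                CopyNumberBin(
                    chrom=str(row.chromosome),
                    start=int(row.start),
                    end=int(row.end),
                    log2=float(row.log2),
                )
            )
        except ValueError as exc:
            raise TableFormatError(f"{path} line {idx}: {exc}") from exc
    return bins


def write_bins(path: PathLike, bins: Sequence[CopyNumberBin]) -> None:
    pd.DataFrame(
        [(b.chrom, b.start, b.end, b.log2) for b in bins], columns=_BIN_COLUMNS
    ).to_csv(path, sep="\t", index=False)


def _opt(value) -> Optional[float]:
    if value is None:
        return None
    value = float(value)
    return None if math.isnan(value) else value


def read_segments(path: PathLike) -> list[CopyNumberSegment]:
    """Read a CNVkit-style ``.cns`` file; ``baf``/CI columns are optional
    and come back missing (``None``) when absent."""
    df = _read_table(path, _SEG_COLUMNS)
    segs = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            segs.append(
                CopyNumberSegment(
                    chrom=str(row.chromosome),
                    start=int(row.start),
                    end=int(row.end),
                    log2=float(row.log2),
                    n_probes=int(row.probes),
                    ci_low=_opt(getattr(row, "ci_lo", None)),
                    ci_high=_opt(getattr(row, "ci_hi", None)),
                    bivar=_opt(getattr(row, "bivar", None)),
                    baf=_opt(getattr(row, "baf", None)),
                )
            )
        except ValueError as exc:
            raise TableFormatError(f"{path} line {idx}: {exc}") from exc
    return segs


def write_segments(path: PathLike, segments: Sequence[CopyNumberSegment]) -> None:
    rows = [
        (
            s.chrom,
            s.start,
            s.end,
            s.log2,
            s.n_probes,
            s.ci_low,
            s.ci_high,
            s.bivar,
            s.baf,
        )
        for s in segments
    ]
    pd.DataFrame(rows, columns=_SEG_COLUMNS + _SEG_OPTIONAL).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# BED and count tables


def read_bed(path: PathLike) -> GenomicIntervalSet:
    """BED3+label (4th column optional) -> GenomicIntervalSet."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except OSError as exc:
        raise TableFormatError(f"cannot read {path}: {exc}") from exc
    if df.shape[1] < 3:
        raise TableFormatError(f"{path}: BED needs at least 3 columns")
    intervals = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        label = str(row[3]) if df.shape[1] >= 4 else ""
        try:
            intervals.append(
                GenomicInterval(
                    chrom=str(row[0]), start=int(row[1]), end=int(row[2]), label=label
                )
            )
        except ValueError as exc:
            raise TableFormatError(f"{path} line {idx}: {exc}") from exc
    return GenomicIntervalSet(intervals)


def write_bed(path: PathLike, intervals: GenomicIntervalSet) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


_COUNT_COLUMNS = ["chrom", "pos", "ref", "alt", "alt_count", "depth"]


def read_counts(path: PathLike) -> dict[AlleleKey, tuple[int, int]]:
    try:
        df = pd.read_csv(path, sep="\t")
    except OSError as exc:
        raise TableFormatError(f"cannot read {path}: {exc}") from exc
    for col in _COUNT_COLUMNS:
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing required column {col!r}")
    return {
        (str(r.chrom), int(r.pos), str(r.ref), str(r.alt)): (
            int(r.alt_count),
            int(r.depth),
        )
        for r in df.itertuples(index=False)
    }


def write_counts(path: PathLike, counts: Mapping[AlleleKey, tuple[int, int]]) -> None:
    rows = [
        (c, p, r, a, alt, depth)
        for (c, p, r, a), (alt, depth) in sorted(counts.items())
    ]
    pd.DataFrame(rows, columns=_COUNT_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Generic flat reports


def write_report(report, path: PathLike) -> None:
    """Serialize any result exposing ``to_frame()`` (or a DataFrame) as TSV
    with a deterministic column order."""
    frame = report.to_frame() if hasattr(report, "to_frame") else report
    if not isinstance(frame, pd.DataFrame):
        raise TypeError(f"cannot serialize {type(report).__name__} as a flat table")
    try:
        frame.to_csv(path, sep="\t", index=False)
    except OSError as exc:
        raise TableFormatError(f"cannot write {path}: {exc}") from exc


def read_report(path: PathLike) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t")
    except OSError as exc:
        raise TableFormatError(f"cannot read {path}: {exc}") from exc


def variants_to_frame(variants: Iterable[VariantCall]) -> pd.DataFrame:
    rows = [
        {
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "vaf": v.vaf,
            "depth": v.depth,
            "ensemble_quality": v.ensemble_quality,
            "gene": v.gene,
            "callers": ",".join(sorted(v.callers)),
            "effect_class": v.effect_class,
        }
        for v in variants
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos",
            "ref",
            "alt",
            "vaf",
            "depth",
            "ensemble_quality",
            "gene",
            "callers",
            "effect_class",
        ],
    )
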