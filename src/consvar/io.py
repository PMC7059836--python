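"""Readers and writers for the standard formats the pipeline touches.

VCF v4.2 (plain or bgzip) is handled through :mod:`pysam`, FASTA through
:mod:`Bio.SeqIO`.  BED is read as plain 3+ column text.  Only the GT field
of genotype columns is interpreted; other FORMAT fields are ignored on read
and not re-emitted.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, Optional

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    OTHER_ALT,
    CallSet,
    Genotype,
    MISSING_GT,
    ReferenceSequence,
    RegionSet,
    VariantSite,
)

log = logging.getLogger(__name__)

#: INFO annotations parsed as numbers by default: the site-level annotations
#: the hard-filter engine computes with.  Everything else is carried opaquely.
NUMERIC_ANNOTATIONS = frozenset({"DP", "MQ", "MQ0F", "HOB", "SGB", "IDV", "IMF"})


# ---------------------------------------------------------------------------
# VCF


def _coerce_info_value(key: str, value, numeric: frozenset, path: str, pos) -> Optional[object]:
    if isinstance(value, tuple):
        value = value[0] if len(value) == 1 else ",".join(str(v) for v in value)
    if key in numeric:
        try:
            return float(value)
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}: unparseable numeric INFO {key}={value!r} at position {pos}"
            ) from None
    if value is True:  # flag
        return "1"
    try:
        return str(value)
    except Exception:  # pragma: no cover - exotic INFO payloads
        log.warning("%s: ignoring unrepresentable INFO field %s at %s", path, key, pos)
        return None


def read_callset(
    path: str,
    label: str,
    reference: Optional[ReferenceSequence] = None,
    numeric_annotations: Iterable[str] = NUMERIC_ANNOTATIONS,
) -> CallSet:
    """Read a VCF v4.2 file (plain or bgzip) into a :class:`CallSet`.

    Sites are re-sorted if the file is out of order (with a warning).  When a
    ``reference`` is given its contig order is authoritative and records on
    contigs absent from it raise.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    numeric = frozenset(numeric_annotations)
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        header_contigs = list(vf.header.contigs)
        sites: list[VariantSite] = []
        genotypes: list[list[Genotype]] = []
        seen_contigs: list[str] = []
        for rec in vf:
            if rec.ref is None or rec.alts is None:
                raise ValueError(f"{path}: record without REF/ALT at line for pos {rec.pos}")
            if reference is not None and rec.contig not in reference:
                raise ValueError(
                    f"{path}: contig {rec.contig!r} not present in the reference"
                )
            info: dict[str, object] = {}
            for key, value in rec.info.items():
                coerced = _coerce_info_value(key, value, numeric, path, rec.pos)
                if coerced is not None:
                    info[key] = coerced
            filters = frozenset(f for f in rec.filter.keys() if f != "PASS")
            site = VariantSite(
                contig=rec.contig,
                pos=rec.pos,
                ref=rec.ref.upper(),
                alts=tuple(a.upper() for a in rec.alts),
                id=rec.id,
                qual=rec.qual,
                filters=filters,
                info=info,
            )
            row: list[Genotype] = []
            for sample in samples:
                call = rec.samples[sample]
                gt = call.get("GT", (None, None))
                if gt is None or all(a is None for a in gt):
                    row.append(MISSING_GT)
                else:
                    a = gt[0]
                    b = gt[1] if len(gt) > 1 else gt[0]
                    row.append(Genotype(a, b, bool(call.phased)))
            sites.append(site)
            genotypes.append(row)
            if rec.contig not in seen_contigs:
                seen_contigs.append(rec.contig)

    if reference is not None:
        contigs = reference.names
    elif header_contigs:
        contigs = header_contigs + [c for c in seen_contigs if c not in header_contigs]
    else:
        contigs = seen_contigs
    cs = CallSet(label=label, samples=samples, sites=sites, genotypes=genotypes, contigs=contigs)
    if not cs.is_sorted():
        log.warning("%s: records out of order; re-sorting", path)
        cs = cs.sorted()
    return cs


def write_callset(
    cs: CallSet,
    path: str,
    reference: Optional[ReferenceSequence] = None,
) -> None:
    """Write a :class:`CallSet` as VCF v4.2.

    Every FILTER label and INFO key in use gets a header line, so that
    ``read_callset(write_callset(cs))`` round-trips.  INFO values are emitted
    as strings; numeric values use a shortest-round-trip format.
    """
    header = pysam.VariantHeader()
    header.add_line("##source=consvar")
    lengths = reference.lengths if reference is not None else {}
    max_pos: dict[str, int] = {}
    for s in cs.sites:
        max_pos[s.contig] = max(max_pos.get(s.contig, 0), s.pos + len(s.ref))
    for contig in cs.contigs:
        header.contigs.add(contig, length=lengths.get(contig, max_pos.get(contig, 1) + 1))
    info_keys: list[str] = []
    filter_labels: list[str] = []
    for s in cs.sites:
        for k in s.info:
            if k not in info_keys:
                info_keys.append(k)
        for f in s.filters:
            if f not in filter_labels:
                filter_labels.append(f)
    info_types = {k: _info_type(cs, k) for k in info_keys}
    for k in info_keys:
        header.info.add(k, 1, info_types[k], "Site annotation")
    for f in filter_labels:
        header.filters.add(f, None, None, "Failed filter")
    header.formats.add("GT", 1, "String", "Genotype")
    for sample in cs.samples:
        header.add_sample(sample)

    with pysam.VariantFile(path, "w", header=header) as out:
        for site, row in zip(cs.sites, cs.genotypes):
            rec = out.new_record(
                contig=site.contig,
                start=site.pos - 1,
                alleles=(site.ref,) + site.alts,
                id=site.id,
                qual=site.qual,
            )
            rec.stop = site.pos - 1 + len(site.ref)
            if site.filters:
                for f in site.filters:
                    rec.filter.add(f)
            else:
                rec.filter.add("PASS")
            for k, v in site.info.items():
                t = info_types[k]
                if t == "Integer":
                    rec.info[k] = int(round(float(v)))
                elif t == "Float":
                    rec.info[k] = float(v)
                else:
                    rec.info[k] = str(v)
            for j, sample in enumerate(cs.samples):
                gt = row[j] if j < len(row) else MISSING_GT
                a = None if gt.a in (None, OTHER_ALT) else gt.a
                b = None if gt.b in (None, OTHER_ALT) else gt.b
                rec.samples[sample]["GT"] = (a, b)
                rec.samples[sample].phased = gt.phased and a is not None and b is not None
            out.write(rec)


def _info_type(cs: CallSet, key: str) -> str:
    """Integer when every value is integral, Float when numeric, else String.

    Fractional values pass through htslib's 32-bit floats, so they round-trip
    at float32 fidelity only; integral and string values round-trip exactly.
    """
    values = [s.info[key] for s in cs.sites if key in s.info]
    if all(isinstance(v, (int, float)) for v in values):
        if all(float(v).is_integer() for v in values):
            return "Integer"
        return "Float"
    return "String"


# ---------------------------------------------------------------------------
# BED


def read_region_set(path: str, class_tag: str) -> RegionSet:
    """Read a BED3+ file (0-based half-open) into a merged :class:`RegionSet`."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            contig, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if start < 0:
                raise ValueError(f"{path}:{lineno}: negative start {start}")
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            intervals.setdefault(contig, []).append((start, end))
    return RegionSet(intervals, class_tag)


def write_region_set(rs: RegionSet, path: str) -> None:
    with open(path, "w") as fh:
        for contig in rs.contigs:
            for s, e in rs.intervals(contig):
                fh.write(f"{contig}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# FASTA


def read_reference(path: str) -> ReferenceSequence:
    """Read a FASTA into a :class:`ReferenceSequence` (names up to whitespace)."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in contigs:
            raise ValueError(f"{path}: duplicate contig name {rec.id!r}")
        contigs[rec.id] = str(rec.seq)
    if not contigs:
        raise ValueError(f"{path}: no FASTA records found")
    return ReferenceSequence(contigs)


def write_reference(ref: ReferenceSequence, path: str) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in ref.contigs.items()]
    SeqIO.write(records, path, "fasta")
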