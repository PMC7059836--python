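"""Canonicalize variant representation across callers.

Different callers describe the same edit in different ways: INDELs placed
anywhere inside a repeat, adjacent SNVs reported as one MNP, co-located
alleles merged into a multiallelic record.  Before call sets can be
compared or unioned they are rewritten into a single canonical form:
left-aligned, trimmed, decomposed into allelic primitives, deduplicated and
restricted to biallelic records.

The left-align/trim loop is the standard one used by ``bcftools norm`` and
``vt normalize``: right-trim shared trailing bases, extending alleles to the
left with reference sequence when one would become empty, then trim shared
leading bases.  The result is the unique minimal left-most representation
of the edit.
"""

from __future__ import annotations

import logging
from collections import Counter

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

__all__ = [
    "left_align_trim",
    "split_multiallelics",
    "merge_multiallelics",
    "decompose_primitives",
    "select_biallelic",
    "exclude_regions",
    "normalize_callset",
]


def left_align_trim(site: VariantSite, ref: ReferenceSequence) -> VariantSite:
    """Rewrite ``site`` into its minimal left-most representation.

    Idempotent and edit-preserving: applying the variant to the reference
    yields the same alternate sequence before and after.  Raises if REF does
    not match the reference sequence, or if left extension is required at
    position 1.
    """
    if site.contig not in ref:
        raise ValueError(f"contig {site.contig!r} not in reference")
    expected = ref.slice(site.contig, site.pos, len(site.ref))
    if expected != site.ref:
        raise ValueError(
            f"REF mismatch at {site.contig}:{site.pos}: site says {site.ref!r}, "
            f"reference has {expected!r}"
        )
    pos = site.pos
    alleles = [site.ref, *site.alts]
    while True:
        last = {a[-1] for a in alleles}
        if len(last) != 1:
            break
        if all(len(a) > 1 for a in alleles):
            alleles = [a[:-1] for a in alleles]
        else:
            if pos == 1:
                raise ValueError(
                    f"cannot left-extend past the start of contig {site.contig!r}"
                )
            pos -= 1
            base = ref.base(site.contig, pos)
            alleles = [base + a[:-1] for a in alleles]
    while all(len(a) > 1 for a in alleles) and len({a[0] for a in alleles}) == 1:
        alleles = [a[1:] for a in alleles]
        pos += 1
    return site.with_(pos=pos, ref=alleles[0], alts=tuple(alleles[1:]))


def split_multiallelics(cs: CallSet, ref: ReferenceSequence | None = None) -> CallSet:
    """Split every multiallelic record into one row per ALT allele.

    Genotype allele indices are re-coded per row: the row's ALT becomes 1 and
    alleles belonging to sibling rows become the :data:`OTHER_ALT` sentinel
    (preserving ploidy for downstream counting).  Rows are re-normalized with
    :func:`left_align_trim` when a reference is supplied.
    """
    sites: list[VariantSite] = []
    genotypes: list[list[Genotype]] = []
    for site, row in zip(cs.sites, cs.genotypes):
        for alt_index, alt in enumerate(site.alts, start=1):
            child = site.with_(alts=(alt,))
            if ref is not None:
                child = left_align_trim(child, ref)
            recoded = [_recode_for_split(gt, alt_index) for gt in row]
            sites.append(child)
            genotypes.append(recoded)
    out = cs.replace(sites=sites, genotypes=genotypes)
    return out.sorted()


def _recode_for_split(gt: Genotype, alt_index: int) -> Genotype:
    if gt.missing:
        return gt

    def recode(a):
        if a == 0:
            return 0
        if a == alt_index:
            return 1
        return OTHER_ALT

    return Genotype(recode(gt.a), recode(gt.b), gt.phased)


def merge_multiallelics(cs: CallSet, ref: ReferenceSequence | None = None) -> CallSet:
    """Merge normalized rows sharing (contig, pos) into multiallelic records.

    Records are extended to a common REF (the longest among the group; each
    shorter REF must be its prefix, which holds for records normalized
    against the same reference) and ALTs are unioned in lexicographic order.
    Merged QUAL is the maximum of the parts, filters are unioned, and INFO
    keys are kept only when identical across parts (others dropped with a
    warning).  Genotypes are reassembled per sample from the per-row calls.
    """
    groups: dict[tuple[str, int], list[int]] = {}
    for i, site in enumerate(cs.sites):
        groups.setdefault((site.contig, site.pos), []).append(i)

    sites: list[VariantSite] = []
    genotypes: list[list[Genotype]] = []
    for key in groups:
        idxs = groups[key]
        if len(idxs) == 1:
            sites.append(cs.sites[idxs[0]])
            genotypes.append(cs.genotypes[idxs[0]])
            continue
        merged_site, merged_gts = _merge_group(
            [cs.sites[i] for i in idxs], [cs.genotypes[i] for i in idxs], len(cs.samples)
        )
        sites.append(merged_site)
        genotypes.append(merged_gts)
    out = cs.replace(sites=sites, genotypes=genotypes)
    return out.sorted()


def _merge_group(group: list[VariantSite], gt_rows: list[list[Genotype]], n_samples: int):
    common_ref = max((s.ref for s in group), key=len)
    for s in group:
        if not common_ref.startswith(s.ref):
            raise ValueError(
                f"cannot merge records at {s.contig}:{s.pos}: REF {s.ref!r} is not a "
                f"prefix of {common_ref!r} (inputs not normalized against one reference?)"
            )
    extended: list[tuple[VariantSite, list[str]]] = []
    all_alts: set[str] = set()
    for s in group:
        suffix = common_ref[len(s.ref) :]
        alts = [a + suffix for a in s.alts]
        extended.append((s, alts))
        all_alts.update(alts)
    alt_order = sorted(all_alts)
    alt_index = {a: i + 1 for i, a in enumerate(alt_order)}

    quals = [s.qual for s in group if s.qual is not None]
    filters = frozenset().union(*(s.filters for s in group))
    info: dict[str, object] = {}
    keysets = [set(s.info) for s in group]
    for k in set().union(*keysets):
        values = [s.info.get(k) for s in group]
        if all(v == values[0] for v in values):
            info[k] = values[0]
        else:
            log.warning(
                "dropping INFO %s at %s:%d on multiallelic merge (conflicting values)",
                k,
                group[0].contig,
                group[0].pos,
            )
    merged_site = group[0].with_(
        ref=common_ref,
        alts=tuple(alt_order),
        qual=max(quals) if quals else None,
        filters=filters,
        info=info,
    )

    merged_gts: list[Genotype] = []
    for j in range(n_samples):
        slots: list = [None, None]
        phased = True
        any_call = False
        for (site, alts), row in zip(extended, gt_rows):
            gt = row[j] if j < len(row) else MISSING_GT
            if gt.missing:
                continue
            any_call = True
            phased = phased and gt.phased
            for h, a in enumerate((gt.a, gt.b)):
                if a == 1:
                    if slots[h] is None or slots[h] == 0:
                        slots[h] = alt_index[alts[0]]
                elif a == 0:
                    if slots[h] is None:
                        slots[h] = 0
                # OTHER_ALT: resolved by the sibling row that owns the allele
        if not any_call:
            merged_gts.append(MISSING_GT)
        else:
            a = slots[0] if slots[0] is not None else 0
            b = slots[1] if slots[1] is not None else 0
            merged_gts.append(Genotype(a, b, phased))
    return merged_site, merged_gts


def decompose_primitives(site: VariantSite) -> list[VariantSite]:
    """Decompose a biallelic complex variant into allelic primitives.

    SNVs and simple INDELs pass through unchanged.  An MNP of length k with
    m mismatching columns yields m SNVs.  A complex substitution (both
    alleles longer than 1, unequal lengths) is aligned prefix-first: SNVs are
    emitted for mismatching shared columns and a single INDEL carries the
    length difference, anchored on the last shared column.  Jointly applying
    the children (INDEL before SNV where they share the anchor position)
    reproduces the parent edit.  QUAL, filters and INFO are copied to every
    child; genotype indices are unchanged (children are biallelic like the
    parent).
    """
    if not site.is_biallelic:
        raise ValueError("decompose_primitives expects a biallelic site")
    ref, alt = site.ref, site.alts[0]
    pos = site.pos
    # shared-end trim (keeping >= 1 base) so pure MNP/INDEL shapes are exposed
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1

    if len(ref) == len(alt):
        if len(ref) == 1:
            return [site.with_(pos=pos, ref=ref, alts=(alt,))]
        children = []
        for i, (r, a) in enumerate(zip(ref, alt)):
            if r != a:
                children.append(site.with_(pos=pos + i, ref=r, alts=(a,)))
        return children
    if len(ref) == 1 or len(alt) == 1:
        return [site.with_(pos=pos, ref=ref, alts=(alt,))]

    # complex: prefix-first alignment, one INDEL for the length difference
    shared = min(len(ref), len(alt))
    children = []
    for i in range(shared - 1):
        if ref[i] != alt[i]:
            children.append(site.with_(pos=pos + i, ref=ref[i], alts=(alt[i],)))
    anchor = shared - 1
    if ref[anchor] != alt[anchor]:
        children.append(site.with_(pos=pos + anchor, ref=ref[anchor], alts=(alt[anchor],)))
    indel_ref = ref[anchor] + ref[shared:]
    indel_alt = ref[anchor] + alt[shared:]
    if indel_ref != indel_alt:
        children.append(site.with_(pos=pos + anchor, ref=indel_ref, alts=(indel_alt,)))
    return children


def select_biallelic(cs: CallSet) -> CallSet:
    """Keep exactly the sites with a single ALT allele (order preserved)."""
    keep = [i for i, s in enumerate(cs.sites) if s.is_biallelic]
    return cs.subset(keep)


def exclude_regions(
    cs: CallSet,
    exclusions: RegionSet | None = None,
    par: RegionSet | None = None,
    sex_contigs: tuple[str, str] = ("chrX", "chrY"),
) -> CallSet:
    """Drop sites in excluded regions and on non-diploid sex-chromosome space.

    Removes every site inside ``exclusions`` (centromere-style intervals),
    every site on the Y chromosome, and X-chromosome sites outside the
    pseudo-autosomal ``par`` intervals.  Removal counts per reason are
    logged.
    """
    chr_x, chr_y = sex_contigs
    keep: list[int] = []
    removed = Counter()
    for i, s in enumerate(cs.sites):
        if exclusions is not None and exclusions.contains(s.contig, s.pos):
            removed["exclusion"] += 1
        elif s.contig == chr_y:
            removed["chrY"] += 1
        elif s.contig == chr_x and not (par is not None and par.contains(s.contig, s.pos)):
            removed["chrX_non_par"] += 1
        else:
            keep.append(i)
    if removed:
        log.info("exclude_regions removed %s", dict(removed))
    return cs.subset(keep)


def normalize_callset(cs: CallSet, ref: ReferenceSequence) -> CallSet:
    """Full canonicalization chain for one call set.

    split multiallelics -> left-align/trim -> decompose primitives -> sort ->
    deduplicate identical site keys (highest QUAL wins, ties keep the first)
    -> re-merge co-located rows -> select biallelic.  Idempotent; output
    sites are unique by :class:`~consvar.model.SiteKey`.  Note that distinct
    alleles sharing a position become multiallelic on the merge step and are
    then discarded by the biallelic selection, as in the upstream protocol.
    """
    cs = cs.replace(contigs=ref.names)
    cs = split_multiallelics(cs, ref)
    sites: list[VariantSite] = []
    genotypes: list[list[Genotype]] = []
    for site, row in zip(cs.sites, cs.genotypes):
        aligned = left_align_trim(site, ref)
        for child in decompose_primitives(aligned):
            sites.append(left_align_trim(child, ref))
            genotypes.append(row)
    cs = cs.replace(sites=sites, genotypes=genotypes).sorted()
    cs = _deduplicate(cs)
    cs = merge_multiallelics(cs, ref)
    return select_biallelic(cs)


def _deduplicate(cs: CallSet) -> CallSet:
    best: dict = {}
    order: list = []
    for i, site in enumerate(cs.sites):
        k = site.key()
        if k not in best:
            best[k] = i
            order.append(k)
        else:
            old = cs.sites[best[k]]
            if (site.qual or 0) > (old.qual or 0):
                best[k] = i
    return cs.subset([best[k] for k in order])
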