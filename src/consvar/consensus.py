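"""Union-based consensus of normalized call sets with per-caller provenance.

The consensus site list is the union of the biallelic site keys across the
supporting call sets.  A :class:`ProvenanceTable` records which callers
contributed each site; its exact-subset counts are the numbers an UpSet
plot displays.  Genotypes of the consensus are reconciled from the
supporters by caller priority (a deterministic stand-in for joint
re-genotyping of the union sites).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .model import CallSet, Genotype, MISSING_GT, SiteKey, VariantSite

log = logging.getLogger(__name__)

__all__ = [
    "ProvenanceTable",
    "union_sites",
    "contribution_counts",
    "reconcile_genotypes",
    "concat_callsets",
    "is_snv_key",
    "split_by_class",
]


@dataclass
class ProvenanceTable:
    """Map from consensus site key to the set of supporting call-set labels."""

    support: dict[SiteKey, frozenset]
    labels: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.support)

    def __getitem__(self, key: SiteKey) -> frozenset:
        return self.support[key]

    def to_rows(self) -> list[tuple[SiteKey, str]]:
        return [(k, ",".join(sorted(v))) for k, v in sorted(self.support.items())]

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("contig\tpos\tref\talt\tsupporting_callsets\n")
            for k, joined in self.to_rows():
                fh.write(f"{k.contig}\t{k.pos}\t{k.ref}\t{k.alt}\t{joined}\n")


def union_sites(callsets: Sequence[CallSet]) -> tuple[CallSet, ProvenanceTable]:
    """Union the biallelic sites of the inputs, tracking provenance.

    Site-level fields of the consensus record: QUAL is the maximum across
    supporters, filters are reset (final filtering happens downstream), and
    INFO keys are kept only when identical across supporters.  Genotypes are
    left missing; use :func:`reconcile_genotypes` to fill them.  The result
    is invariant under permutation of the inputs.
    """
    if not callsets:
        raise ValueError("union_sites needs at least one call set")
    for cs in callsets:
        for s in cs.sites:
            if not s.is_biallelic:
                raise ValueError(
                    f"{cs.label}: non-biallelic site at {s.contig}:{s.pos}; "
                    "normalize call sets before building the union"
                )
    support: dict[SiteKey, set] = {}
    parts: dict[SiteKey, list[VariantSite]] = {}
    contigs: list[str] = []
    samples = callsets[0].samples
    for cs in callsets:
        for c in cs.contigs:
            if c not in contigs:
                contigs.append(c)
        for s in cs.sites:
            k = s.key()
            support.setdefault(k, set()).add(cs.label)
            parts.setdefault(k, []).append(s)

    sites: list[VariantSite] = []
    for k in support:
        group = parts[k]
        quals = [s.qual for s in group if s.qual is not None]
        info: dict[str, object] = {}
        for key in set().union(*(set(s.info) for s in group)):
            values = [s.info.get(key) for s in group]
            if all(v == values[0] for v in values):
                info[key] = values[0]
        sites.append(
            group[0].with_(
                qual=max(quals) if quals else None,
                filters=frozenset(),
                info=info,
            )
        )
    consensus = CallSet(
        label="consensus",
        samples=list(samples),
        sites=sites,
        genotypes=[[MISSING_GT] * len(samples) for _ in sites],
        contigs=contigs,
    ).sorted()
    table = ProvenanceTable(
        support={k: frozenset(v) for k, v in support.items()},
        labels=tuple(cs.label for cs in callsets),
    )
    return consensus, table


def contribution_counts(
    prov: ProvenanceTable,
) -> tuple[dict[frozenset, int], dict[str, int]]:
    """Exact-subset intersection counts (UpSet bars) and per-label marginals.

    The first map counts keys by the exact set of supporting labels (vertical
    bars of an UpSet plot; counts sum to the consensus size); the second
    gives each label's total contribution (horizontal bars).
    """
    subsets: dict[frozenset, int] = {}
    marginals: dict[str, int] = {label: 0 for label in prov.labels}
    for labels in prov.support.values():
        subsets[labels] = subsets.get(labels, 0) + 1
        for label in labels:
            marginals[label] = marginals.get(label, 0) + 1
    return subsets, marginals


def reconcile_genotypes(
    consensus: CallSet,
    callsets: Sequence[CallSet],
    priority: Sequence[str],
) -> CallSet:
    """Fill consensus genotypes by caller priority.

    For each consensus site and sample the genotype is taken from the
    highest-priority call set that contains the site with a non-missing call
    for that sample; otherwise it stays missing.  Samples are resolved by
    name intersection (warning when the inputs disagree).
    """
    by_label = {cs.label: cs for cs in callsets}
    missing = [lab for lab in by_label if lab not in priority]
    if missing:
        raise ValueError(f"priority does not cover call sets: {missing}")
    ordered = [by_label[lab] for lab in priority if lab in by_label]

    samples = list(consensus.samples)
    for cs in ordered:
        if list(cs.samples) != samples:
            shared = [s for s in samples if s in cs.samples]
            if shared != samples:
                log.warning(
                    "sample sets differ (%s vs consensus); using the intersection",
                    cs.label,
                )
                samples = shared
    lookups = [({s.key(): i for i, s in enumerate(cs.sites)}, cs) for cs in ordered]

    genotypes: list[list[Genotype]] = []
    for site in consensus.sites:
        k = site.key()
        row: list[Genotype] = []
        for sample in samples:
            chosen = MISSING_GT
            for index, cs in lookups:
                i = index.get(k)
                if i is None:
                    continue
                j = cs.samples.index(sample)
                gt = cs.genotypes[i][j]
                if not gt.missing:
                    chosen = gt
                    break
            row.append(chosen)
        genotypes.append(row)
    return consensus.replace(samples=samples, genotypes=genotypes)


def concat_callsets(a: CallSet, b: CallSet) -> CallSet:
    """Concatenate two call sets (e.g. the SNV-only and INDEL-only consensus).

    The inputs must carry the same samples (order differences are fixed up
    with a log message).  Duplicate site keys collapse to the first record
    with a warning; the result is sorted.
    """
    if set(a.samples) != set(b.samples):
        raise ValueError("concat_callsets requires identical sample sets")
    if a.samples != b.samples:
        log.info("concat_callsets: re-ordering samples of %s to match %s", b.label, a.label)
        order = [b.samples.index(s) for s in a.samples]
        b = b.replace(
            samples=list(a.samples),
            genotypes=[[row[i] for i in order] for row in b.genotypes],
        )
    contigs = list(a.contigs) + [c for c in b.contigs if c not in a.contigs]
    seen: set[SiteKey] = set()
    sites: list[VariantSite] = []
    genotypes: list[list[Genotype]] = []
    for cs in (a, b):
        for site, row in zip(cs.sites, cs.genotypes):
            k = site.key()
            if k in seen:
                log.warning("concat_callsets: duplicate site %s; keeping the first", (k,))
                continue
            seen.add(k)
            sites.append(site)
            genotypes.append(row)
    return CallSet(
        label=a.label,
        samples=list(a.samples),
        sites=sites,
        genotypes=genotypes,
        contigs=contigs,
    ).sorted()


def is_snv_key(key: SiteKey) -> bool:
    """SNV iff both alleles are single bases; everything else routes as INDEL."""
    return len(key.ref) == 1 and len(key.alt) == 1


def split_by_class(cs: CallSet) -> tuple[CallSet, CallSet]:
    """Split a biallelic call set into its SNV and INDEL subsets."""
    snv = [i for i, s in enumerate(cs.sites) if is_snv_key(s.key())]
    indel = [i for i in range(len(cs.sites)) if i not in set(snv)]
    return cs.subset(snv), cs.subset(indel)
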