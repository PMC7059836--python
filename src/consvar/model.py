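"""Core domain types for the consensus variant-calling pipeline.

Coordinates follow the two standards they come from: VCF records are
1-based inclusive, BED intervals are 0-based half-open.  The conversion
between the two happens in exactly one place, :meth:`RegionSet.contains`,
which takes a 1-based VCF position and tests ``pos - 1`` against the
half-open intervals.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, NamedTuple, Optional, Sequence

__all__ = [
    "OTHER_ALT",
    "ALPHABET",
    "ReferenceSequence",
    "VariantSite",
    "Genotype",
    "CallSet",
    "RegionSet",
    "SiteKey",
]

ALPHABET = frozenset("ACGTN")

#: Sentinel allele index used when a multiallelic genotype is re-coded during
#: a split and the called allele belongs to a different output row.
OTHER_ALT = -2


class SiteKey(NamedTuple):
    """Identity of a normalized biallelic record.

    All site-level matching in the pipeline (union consensus, TP/FP/FN
    labelling, switch-error pairing) is done under this key.
    """

    contig: str
    pos: int
    ref: str
    alt: str


class Genotype(NamedTuple):
    """A diploid call for one sample: two allele indices and a phase flag.

    ``a == b == None`` encodes a missing call.  Allele indices refer to the
    site's allele list (0 = REF, 1 = first ALT, ...); :data:`OTHER_ALT`
    marks an allele that belongs to a sibling row after a multiallelic
    split.
    """

    a: Optional[int]
    b: Optional[int]
    phased: bool = False

    @property
    def missing(self) -> bool:
        return self.a is None and self.b is None

    def is_het(self) -> bool:
        return not self.missing and self.a != self.b

    def unphased_key(self) -> Optional[frozenset]:
        if self.missing:
            return None
        return frozenset((self.a, self.b)) if self.a != self.b else frozenset((self.a,))


MISSING_GT = Genotype(None, None, False)


class ReferenceSequence:
    """An in-memory reference genome: contig name -> uppercase sequence.

    The contig order of the FASTA defines the global sort order for every
    call set in a run.
    """

    def __init__(self, contigs: Mapping[str, str]):
        seen: dict[str, str] = {}
        for name, seq in contigs.items():
            if name in seen:
                raise ValueError(f"duplicate contig name: {name!r}")
            if not seq:
                raise ValueError(f"empty sequence for contig {name!r}")
            seq = seq.upper()
            bad = set(seq) - ALPHABET
            if bad:
                raise ValueError(f"contig {name!r} contains non-ACGTN characters: {sorted(bad)}")
            seen[name] = seq
        self._contigs = seen
        self._order = {name: i for i, name in enumerate(seen)}

    @property
    def contigs(self) -> Mapping[str, str]:
        return dict(self._contigs)

    @property
    def names(self) -> list[str]:
        return list(self._contigs)

    def __contains__(self, name: str) -> bool:
        return name in self._contigs

    def __getitem__(self, name: str) -> str:
        return self._contigs[name]

    def length(self, name: str) -> int:
        return len(self._contigs[name])

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self._contigs.items()}

    def contig_index(self, name: str) -> int:
        try:
            return self._order[name]
        except KeyError:
            raise KeyError(f"contig {name!r} not present in reference") from None

    def base(self, contig: str, pos: int) -> str:
        """Base at 1-based position ``pos``."""
        return self._contigs[contig][pos - 1]

    def slice(self, contig: str, pos: int, length: int) -> str:
        """``length`` bases starting at 1-based ``pos``."""
        return self._contigs[contig][pos - 1 : pos - 1 + length]


@dataclass(frozen=True)
class VariantSite:
    """One VCF record: position, alleles, quality, filters and annotations.

    ``filters`` holds failure labels only; an empty set means PASS.  ``info``
    maps annotation name to a float for the annotations the pipeline computes
    with (DP, MQ, ...), and to an opaque string for everything else carried
    through from the input.
    """

    contig: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    id: Optional[str] = None
    qual: Optional[float] = None
    filters: frozenset = frozenset()
    info: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if not self.ref:
            raise ValueError("REF allele must be non-empty")
        if not self.alts:
            raise ValueError("site must carry at least one ALT allele")
        if any(a == self.ref for a in self.alts):
            raise ValueError(f"ALT equals REF at {self.contig}:{self.pos}")
        if self.qual is not None and self.qual < 0:
            raise ValueError("QUAL must be non-negative")

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1

    @property
    def is_snv(self) -> bool:
        return self.is_biallelic and len(self.ref) == 1 and len(self.alts[0]) == 1

    @property
    def is_pass(self) -> bool:
        return not self.filters

    def key(self) -> SiteKey:
        if not self.is_biallelic:
            raise ValueError("SiteKey is only defined for biallelic sites")
        return SiteKey(self.contig, self.pos, self.ref, self.alts[0])

    def with_(self, **kw) -> "VariantSite":
        return replace(self, **kw)


@dataclass
class CallSet:
    """An ordered collection of sites with per-sample genotypes.

    ``genotypes[i][j]`` is the call of sample ``j`` at site ``i``.  ``contigs``
    records the contig sort order in force (normally the reference FASTA
    order).  ``metadata`` is a free-form scratch area (the simulator uses it
    to record ground truth for testing); it is never serialized.
    """

    label: str
    samples: list[str]
    sites: list[VariantSite]
    genotypes: list[list[Genotype]]
    contigs: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.sites) != len(self.genotypes):
            raise ValueError("genotypes must align with sites")
        if not self.contigs:
            seen: list[str] = []
            for s in self.sites:
                if s.contig not in seen:
                    seen.append(s.contig)
            self.contigs = seen

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self) -> Iterator[VariantSite]:
        return iter(self.sites)

    def contig_index(self, name: str) -> int:
        try:
            return self.contigs.index(name)
        except ValueError:
            raise KeyError(f"contig {name!r} not registered in call set") from None

    def sort_key(self, site: VariantSite):
        return (self.contig_index(site.contig), site.pos, site.ref, site.alts)

    def sorted(self) -> "CallSet":
        order = sorted(range(len(self.sites)), key=lambda i: self.sort_key(self.sites[i]))
        return replace(
            self,
            sites=[self.sites[i] for i in order],
            genotypes=[self.genotypes[i] for i in order],
        )

    def is_sorted(self) -> bool:
        keys = [self.sort_key(s) for s in self.sites]
        return all(keys[i] <= keys[i + 1] for i in range(len(keys) - 1))

    def keys(self) -> list[SiteKey]:
        return [s.key() for s in self.sites]

    def key_set(self) -> set[SiteKey]:
        return set(self.keys())

    def subset(self, indices: Sequence[int]) -> "CallSet":
        return replace(
            self,
            sites=[self.sites[i] for i in indices],
            genotypes=[self.genotypes[i] for i in indices],
        )

    def replace(self, **kw) -> "CallSet":
        return replace(self, **kw)


class RegionSet:
    """Per-contig merged intervals with a class tag.

    Intervals are 0-based half-open (BED convention).  Overlapping or
    book-ended input intervals are merged on construction, so membership is
    a binary search over disjoint intervals.
    """

    CLASS_TAGS = ("confidence", "exclusion", "novel", "par")

    def __init__(self, intervals: Mapping[str, Iterable[tuple[int, int]]], class_tag: str):
        if class_tag not in self.CLASS_TAGS:
            raise ValueError(f"unknown region class {class_tag!r}")
        self.class_tag = class_tag
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for contig, ivs in intervals.items():
            merged = _merge_intervals(ivs)
            if merged:
                self._starts[contig] = [s for s, _ in merged]
                self._ends[contig] = [e for _, e in merged]

    @property
    def contigs(self) -> list[str]:
        return list(self._starts)

    def intervals(self, contig: str) -> list[tuple[int, int]]:
        if contig not in self._starts:
            return []
        return list(zip(self._starts[contig], self._ends[contig]))

    def contains_point(self, contig: str, pos0: int) -> bool:
        """Membership of a 0-based coordinate."""
        starts = self._starts.get(contig)
        if not starts:
            return False
        i = bisect.bisect_right(starts, pos0) - 1
        return i >= 0 and pos0 < self._ends[contig][i]

    def contains(self, contig: str, pos: int) -> bool:
        """Membership of a 1-based VCF position (the only 1->0 conversion)."""
        return self.contains_point(contig, pos - 1)

    def covered_length(self, contig: Optional[str] = None) -> int:
        if contig is not None:
            return sum(e - s for s, e in self.intervals(contig))
        return sum(self.covered_length(c) for c in self.contigs)

    def __bool__(self) -> bool:
        return bool(self._starts)


def _merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if s < 0:
            raise ValueError(f"negative interval start {s}")
        if s >= e:
            raise ValueError(f"empty or inverted interval ({s}, {e})")
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out
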