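"""Synthetic multi-caller data with known truth.

Everything the pipeline consumes can be generated here: a toy diploid
reference, a phased truth panel in Hardy-Weinberg equilibrium, region sets
(confidence / exclusion / PAR / novel), a gold standard, and several
simulated callers that share the truth but differ in sensitivity,
false-positive rate and, crucially, variant *representation*:

* ``right_shifted`` callers place INDELs at the right edge of the
  homopolymer run that contains them (truth is left-aligned),
* ``mnp_joined`` callers report adjacent SNV pairs as one MNP,
* ``multiallelic_merged`` callers merge adjacent SNV pairs into one padded
  multiallelic record.

All of these normalize back to the truth representation, which is the
central identity the integration pipeline must preserve.  Truth sites are
laid out on a fixed-width slot grid so that planted homopolymer runs, MNP
pairs and false-positive placements can never collide; every operation is a
pure function of its inputs and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .model import CallSet, Genotype, MISSING_GT, ReferenceSequence, RegionSet, VariantSite

log = logging.getLogger(__name__)

__all__ = [
    "AnnotationLaw",
    "CallerProfile",
    "SimulationConfig",
    "generate_truth",
    "simulate_caller",
    "simulate_phasing",
    "generate_gold",
    "default_caller_profiles",
]

BASES = np.array(list("ACGT"))
SLOT = 16  # grid pitch (bp); wide enough for an anchor + run + clearance

REPRESENTATION_STYLES = ("canonical", "right_shifted", "mnp_joined", "multiallelic_merged")


@dataclass(frozen=True)
class AnnotationLaw:
    """Gaussian annotation model: separate means/sds for TP and FP sites.

    ``low``/``high`` clip the draws to the annotation's natural range.
    """

    tp_mean: float
    tp_sd: float
    fp_mean: float
    fp_sd: float
    low: float = -np.inf
    high: float = np.inf
    integer: bool = False  # count-valued annotations (read depths)

    def draw(self, rng: np.random.Generator, is_tp: bool) -> float:
        mu, sd = (self.tp_mean, self.tp_sd) if is_tp else (self.fp_mean, self.fp_sd)
        v = float(np.clip(rng.normal(mu, sd), self.low, self.high))
        return float(round(v)) if self.integer else v


def _default_laws() -> dict[str, AnnotationLaw]:
    # TP/FP separation mirrors the shape of the production annotations:
    # depth blow-ups, low mapping quality and segregation-bias extremes mark
    # false calls.
    return {
        "QUAL": AnnotationLaw(90, 25, 35, 20, low=0),
        "DP": AnnotationLaw(300, 60, 900, 300, low=0, integer=True),
        "MQ": AnnotationLaw(55, 3, 30, 5, low=0, high=60),
        "MQ0F": AnnotationLaw(0.01, 0.01, 0.15, 0.05, low=0, high=1),
        "HOB": AnnotationLaw(0.05, 0.03, 0.30, 0.08, low=0, high=1),
        "SGB": AnnotationLaw(0, 500, 4000, 800),
    }


def _default_indel_laws() -> dict[str, AnnotationLaw]:
    return {
        "IDV": AnnotationLaw(20, 5, 80, 15, low=0, integer=True),
        "IMF": AnnotationLaw(0.8, 0.1, 0.2, 0.1, low=0, high=1),
    }


@dataclass(frozen=True)
class CallerProfile:
    """Behaviour of one simulated caller.

    ``sensitivity`` is the per-site inclusion probability for truth sites,
    ``fdr`` the expected fraction of emitted sites that are false, and
    ``representation_style`` the rewriting applied to included truth sites.
    ``absent_contigs`` models a caller blind to certain sequence (a lift-over
    cannot place calls on novel contigs).
    """

    label: str
    sensitivity: float = 0.95
    fdr: float = 0.02
    representation_style: str = "canonical"
    absent_contigs: tuple[str, ...] = ()
    laws: dict[str, AnnotationLaw] = field(default_factory=_default_laws)
    indel_laws: dict[str, AnnotationLaw] = field(default_factory=_default_indel_laws)

    def __post_init__(self):
        if not 0 < self.sensitivity <= 1:
            raise ValueError("sensitivity must lie in (0, 1]")
        if not 0 <= self.fdr < 1:
            raise ValueError("fdr must lie in [0, 1)")
        if self.representation_style not in REPRESENTATION_STYLES:
            raise ValueError(f"unknown representation style {self.representation_style!r}")


def default_caller_profiles() -> list[CallerProfile]:
    """Four callers emulating the production mix of sensitivities and styles."""
    return [
        CallerProfile("gatk", sensitivity=0.95, fdr=0.02, representation_style="canonical"),
        CallerProfile("freebayes", sensitivity=0.92, fdr=0.03, representation_style="mnp_joined"),
        CallerProfile("lc_bcftools", sensitivity=0.90, fdr=0.05, representation_style="right_shifted"),
        CallerProfile(
            "ex_bcftools", sensitivity=0.60, fdr=0.02, representation_style="multiallelic_merged"
        ),
    ]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study.

    Site-class fractions are fractions of ``n_sites``; MNP-source and
    merge-source sites come in adjacent same-genotype pairs, so their
    fractions are realized in units of two sites.  Allele frequencies follow
    a Beta law and genotypes are drawn haplotype-wise (Hardy-Weinberg).
    Region fractions state the covered share of each contig (PAR: of the X
    chromosome; the designated novel contig is covered entirely by the novel
    region class).
    """

    seed: int = 0
    contigs: tuple[tuple[str, int], ...] = (
        ("chr1", 120_000),
        ("chr2", 100_000),
        ("chr20", 80_000),
        ("chrX", 60_000),
        ("chrY", 30_000),
        ("chr1_novel", 40_000),
    )
    n_samples: int = 10
    n_sites: int = 4000
    indel_fraction: float = 0.12
    mnp_fraction: float = 0.08
    multiallelic_fraction: float = 0.06
    af_beta: tuple[float, float] = (0.8, 0.8)
    phase_flip_rate: float = 0.02
    confidence_fraction: float = 0.85
    exclusion_fraction: float = 0.05
    par_fraction: float = 0.3
    novel_contig: str = "chr1_novel"
    caller_profiles: tuple[CallerProfile, ...] = field(
        default_factory=lambda: tuple(default_caller_profiles())
    )

    def __post_init__(self):
        for name, frac in (
            ("indel_fraction", self.indel_fraction),
            ("mnp_fraction", self.mnp_fraction),
            ("multiallelic_fraction", self.multiallelic_fraction),
            ("confidence_fraction", self.confidence_fraction),
            ("exclusion_fraction", self.exclusion_fraction),
            ("par_fraction", self.par_fraction),
        ):
            if not 0 <= frac <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.indel_fraction + self.mnp_fraction + self.multiallelic_fraction > 1:
            raise ValueError("site-class fractions exceed 1")
        if not 0 <= self.phase_flip_rate < 0.5:
            raise ValueError("phase_flip_rate must lie in [0, 0.5)")
        for name, length in self.contigs:
            if length < 100:
                raise ValueError(f"contig {name!r} too short (< 100 bp)")


# ---------------------------------------------------------------------------
# truth generation


def _slot_grid(contigs: Sequence[tuple[str, int]]) -> list[tuple[str, int]]:
    """All (contig, anchor_pos) slots; anchors are 1-based and SLOT apart."""
    slots = []
    for name, length in contigs:
        pos = SLOT
        while pos + SLOT < length:
            slots.append((name, pos))
            pos += SLOT
    return slots


def generate_truth(
    cfg: SimulationConfig,
) -> tuple[ReferenceSequence, CallSet, dict[str, RegionSet]]:
    """Generate the reference, the phased truth panel and the region bundle.

    Truth sites are biallelic and canonical (left-aligned, trimmed).  The
    returned region dict has keys ``confidence``, ``exclusion``, ``par`` and
    ``novel``.  ``truth.metadata`` records allele frequencies, per-site
    class, pair structure and the free slots available for false-positive
    placement.
    """
    rng = np.random.default_rng(cfg.seed)
    seqs = {name: rng.choice(BASES, size=length) for name, length in cfg.contigs}

    slots = _slot_grid(cfg.contigs)
    n_mnp_pairs = int(round(cfg.mnp_fraction * cfg.n_sites / 2))
    n_mal_pairs = int(round(cfg.multiallelic_fraction * cfg.n_sites / 2))
    n_indel = int(round(cfg.indel_fraction * cfg.n_sites))
    n_snv = cfg.n_sites - 2 * (n_mnp_pairs + n_mal_pairs) - n_indel
    n_slots = n_snv + n_indel + n_mnp_pairs + n_mal_pairs
    if n_slots > len(slots):
        raise ValueError(
            f"site density infeasible: {n_slots} slots needed, {len(slots)} available"
        )
    chosen = rng.choice(len(slots), size=n_slots, replace=False)
    chosen_slots = [slots[i] for i in sorted(chosen)]
    free_slots = [slots[i] for i in sorted(set(range(len(slots))) - set(chosen))]
    classes = (
        ["snv"] * n_snv + ["indel"] * n_indel + ["mnp_pair"] * n_mnp_pairs + ["mal_pair"] * n_mal_pairs
    )
    rng.shuffle(classes)

    a, b = cfg.af_beta
    samples = [f"S{i:03d}" for i in range(cfg.n_samples)]
    order = {name: i for i, (name, _) in enumerate(cfg.contigs)}
    contig_names = [name for name, _ in cfg.contigs]

    site_specs: list[dict] = []  # one spec per emitted truth record
    pair_of: dict[int, tuple[int, str]] = {}  # site index -> (partner index, kind)

    def draw_genotypes(p: float) -> list[Genotype]:
        haps = rng.random((cfg.n_samples, 2)) < p
        return [Genotype(int(h[0]), int(h[1]), True) for h in haps]

    for (contig, pos), cls in zip(chosen_slots, classes):
        seq = seqs[contig]
        p = float(rng.beta(a, b))
        if cls == "snv":
            ref_base = str(seq[pos - 1])
            alt = str(rng.choice(BASES[BASES != ref_base]))
            site_specs.append(
                dict(contig=contig, pos=pos, ref=ref_base, alt=alt, cls="snv",
                     af=p, genotypes=draw_genotypes(p))
            )
        elif cls == "indel":
            run_base = str(rng.choice(BASES))
            k = int(rng.integers(3, 6))
            # run occupies pos+1 .. pos+k; anchor and the base after must differ
            seq[pos : pos + k] = run_base
            if str(seq[pos - 1]) == run_base:
                seq[pos - 1] = rng.choice(BASES[BASES != run_base])
            if str(seq[pos + k]) == run_base:
                seq[pos + k] = rng.choice(BASES[BASES != run_base])
            anchor = str(seq[pos - 1])
            if rng.random() < 0.5:  # deletion of one run copy
                ref_a, alt_a = anchor + run_base, anchor
            else:  # insertion of one run copy
                ref_a, alt_a = anchor, anchor + run_base
            site_specs.append(
                dict(contig=contig, pos=pos, ref=ref_a, alt=alt_a, cls="indel",
                     af=p, genotypes=draw_genotypes(p), run=(run_base, k))
            )
        else:  # adjacent same-genotype SNV pair (MNP source or merge source)
            kind = "mnp" if cls == "mnp_pair" else "mal"
            gts = draw_genotypes(p)
            r1, r2 = str(seq[pos - 1]), str(seq[pos])
            a1 = str(rng.choice(BASES[BASES != r1]))
            a2 = str(rng.choice(BASES[BASES != r2]))
            i0 = len(site_specs)
            site_specs.append(
                dict(contig=contig, pos=pos, ref=r1, alt=a1, cls=f"{kind}_pair",
                     af=p, genotypes=gts)
            )
            site_specs.append(
                dict(contig=contig, pos=pos + 1, ref=r2, alt=a2, cls=f"{kind}_pair",
                     af=p, genotypes=list(gts))
            )
            pair_of[i0] = (i0 + 1, kind)
            pair_of[i0 + 1] = (i0, kind)

    ref = ReferenceSequence({name: "".join(seqs[name]) for name, _ in cfg.contigs})

    sort_idx = sorted(
        range(len(site_specs)),
        key=lambda i: (order[site_specs[i]["contig"]], site_specs[i]["pos"]),
    )
    remap = {old: new for new, old in enumerate(sort_idx)}
    specs = [site_specs[i] for i in sort_idx]
    pairs = {remap[i]: (remap[j], kind) for i, (j, kind) in pair_of.items()}

    sites = [
        VariantSite(contig=s["contig"], pos=s["pos"], ref=s["ref"], alts=(s["alt"],))
        for s in specs
    ]
    genotypes = [s["genotypes"] for s in specs]
    truth = CallSet(
        label="truth",
        samples=samples,
        sites=sites,
        genotypes=genotypes,
        contigs=contig_names,
        metadata={
            "af": [s["af"] for s in specs],
            "site_class": [s["cls"] for s in specs],
            "runs": {i: s["run"] for i, s in enumerate(specs) if "run" in s},
            "pairs": pairs,
            "free_slots": free_slots,
            "config": cfg,
        },
    ).sorted()

    regions = _region_bundle(cfg)
    return ref, truth, regions


def _region_bundle(cfg: SimulationConfig) -> dict[str, RegionSet]:
    confidence: dict[str, list[tuple[int, int]]] = {}
    exclusion: dict[str, list[tuple[int, int]]] = {}
    for name, length in cfg.contigs:
        f = cfg.confidence_fraction
        lo = int(length * (1 - f) / 2)
        confidence[name] = [(lo, lo + int(length * f))]
        if cfg.exclusion_fraction > 0:
            e = cfg.exclusion_fraction
            mid = int(length * (0.5 - e / 2))
            exclusion[name] = [(mid, mid + int(length * e))]
    par: dict[str, list[tuple[int, int]]] = {}
    x_len = dict(cfg.contigs).get("chrX")
    if x_len:
        par["chrX"] = [(0, int(x_len * cfg.par_fraction))]
    novel: dict[str, list[tuple[int, int]]] = {}
    novel_len = dict(cfg.contigs).get(cfg.novel_contig)
    if novel_len:
        novel[cfg.novel_contig] = [(0, novel_len)]
    return {
        "confidence": RegionSet(confidence, "confidence"),
        "exclusion": RegionSet(exclusion, "exclusion"),
        "par": RegionSet(par, "par"),
        "novel": RegionSet(novel, "novel"),
    }


# ---------------------------------------------------------------------------
# simulated callers


def simulate_caller(
    truth: CallSet,
    profile: CallerProfile,
    ref: ReferenceSequence,
    seed: int,
) -> CallSet:
    """Emit one caller's view of the truth.

    Each truth site is included independently with probability
    ``profile.sensitivity`` (zero on ``absent_contigs``); false sites are
    added at free slots so the expected false fraction of emitted sites is
    ``profile.fdr``.  Included sites are rewritten per the representation
    style, and QUAL plus the filterable annotations are drawn from the
    profile's TP/FP laws.  ``metadata['truth_keys']`` / ``['fp_keys']``
    record ground-truth membership (canonical keys) for testing.
    """
    rng = np.random.default_rng(seed)
    pairs: dict[int, tuple[int, str]] = truth.metadata.get("pairs", {})
    runs: dict[int, tuple[str, int]] = truth.metadata.get("runs", {})

    include = rng.random(len(truth)) < profile.sensitivity
    for i, s in enumerate(truth.sites):
        if s.contig in profile.absent_contigs:
            include[i] = False

    records: list[tuple[VariantSite, list[Genotype], bool]] = []
    consumed: set[int] = set()
    truth_keys: set = set()
    for i, (site, row) in enumerate(zip(truth.sites, truth.genotypes)):
        if not include[i] or i in consumed:
            continue
        truth_keys.add(site.key())
        partner = pairs.get(i)
        style = profile.representation_style
        if style == "right_shifted" and i in runs:
            records.append((_right_shift(site, runs[i], ref), row, True))
        elif style in ("mnp_joined", "multiallelic_merged") and partner is not None:
            j, kind = partner
            joinable = (
                include[j]
                and j == i + 1
                and ((style == "mnp_joined") == (kind == "mnp"))
            )
            if joinable:
                consumed.add(j)
                truth_keys.add(truth.sites[j].key())
                if style == "mnp_joined":
                    records.append((_join_mnp(site, truth.sites[j]), row, True))
                else:
                    merged = _merge_pair(site, truth.sites[j])
                    records.append((merged, _merged_pair_genotypes(row), True))
            else:
                records.append((site, row, True))
        else:
            records.append((site, row, True))

    n_true = len(records)
    n_fp = int(round(n_true * profile.fdr / (1 - profile.fdr))) if profile.fdr > 0 else 0
    fp_records, fp_keys = _place_false_sites(truth, profile, ref, rng, n_fp)
    records.extend(fp_records)

    cfg = truth.metadata.get("config")
    indel_capable = cfg is None or cfg.indel_fraction > 0
    if profile.representation_style == "right_shifted" and not runs and not indel_capable:
        log.info("%s: no homopolymer context available; emitting canonical", profile.label)

    sites: list[VariantSite] = []
    genotypes: list[list[Genotype]] = []
    for site, row, is_tp in records:
        info = {k: law.draw(rng, is_tp) for k, law in profile.laws.items() if k != "QUAL"}
        if not site.is_snv:
            info.update({k: law.draw(rng, is_tp) for k, law in profile.indel_laws.items()})
        qual_law = profile.laws.get("QUAL", AnnotationLaw(90, 25, 35, 20, low=0))
        sites.append(site.with_(qual=qual_law.draw(rng, is_tp), info=info))
        genotypes.append(row)

    cs = CallSet(
        label=profile.label,
        samples=list(truth.samples),
        sites=sites,
        genotypes=genotypes,
        contigs=list(truth.contigs),
        metadata={"truth_keys": truth_keys, "fp_keys": fp_keys, "profile": profile},
    ).sorted()
    return cs


def _right_shift(site: VariantSite, run: tuple[str, int], ref: ReferenceSequence) -> VariantSite:
    """Rewrite a left-aligned run INDEL to the right edge of its run."""
    run_base, k = run
    s = site.pos + 1  # run start (1-based)
    nxt = ref.base(site.contig, s + k)
    if len(site.ref) > len(site.alts[0]):  # deletion: drop the last run copy
        return site.with_(pos=s + k - 1, ref=run_base + nxt, alts=(nxt,))
    # insertion: duplicate the last run copy
    return site.with_(pos=s + k - 1, ref=run_base, alts=(run_base + run_base,))


def _join_mnp(first: VariantSite, second: VariantSite) -> VariantSite:
    return first.with_(ref=first.ref + second.ref, alts=(first.alts[0] + second.alts[0],))


def _merge_pair(first: VariantSite, second: VariantSite) -> VariantSite:
    ref = first.ref + second.ref
    alts = tuple(sorted((first.alts[0] + second.ref, first.ref + second.alts[0])))
    return first.with_(ref=ref, alts=alts)


def _merged_pair_genotypes(row: list[Genotype]) -> list[Genotype]:
    # The two sites share genotypes; a haplotype carrying both alternates has
    # no representable allele in the padded record, so alt 1 wins (lossy,
    # site-key identity is unaffected).
    out = []
    for gt in row:
        if gt.missing:
            out.append(gt)
        else:
            out.append(Genotype(min(gt.a, 1), min(gt.b, 1), gt.phased))
    return out


def _place_false_sites(
    truth: CallSet,
    profile: CallerProfile,
    ref: ReferenceSequence,
    rng: np.random.Generator,
    n_fp: int,
) -> tuple[list[tuple[VariantSite, list[Genotype], bool]], set]:
    free_slots: list[tuple[str, int]] = [
        (c, p)
        for c, p in truth.metadata.get("free_slots", [])
        if c not in profile.absent_contigs
    ]
    if n_fp > len(free_slots):
        raise ValueError("false-positive budget exceeds the free slots available")
    if n_fp == 0:
        return [], set()
    cfg = truth.metadata.get("config")
    indel_frac = cfg.indel_fraction if cfg is not None else 0.1
    picks = rng.choice(len(free_slots), size=n_fp, replace=False)
    records = []
    keys = set()
    n_samples = len(truth.samples)
    for idx in picks:
        contig, pos = free_slots[idx]
        ref_base = ref.base(contig, pos)
        if rng.random() < indel_frac:
            # insertion anchored on reference context; the inserted base
            # differs from the anchor so the record is already canonical
            ins = str(rng.choice(BASES[BASES != ref_base]))
            site = VariantSite(contig=contig, pos=pos, ref=ref_base, alts=(ref_base + ins,))
        else:
            alt = str(rng.choice(BASES[BASES != ref_base]))
            site = VariantSite(contig=contig, pos=pos, ref=ref_base, alts=(alt,))
        carriers = rng.random(n_samples) < 0.2
        carriers[rng.integers(n_samples)] = True
        row = [
            Genotype(0, 1, False) if c else Genotype(0, 0, False) for c in carriers
        ]
        records.append((site, row, False))
        keys.add(site.key())
    return records, keys


# ---------------------------------------------------------------------------
# phasing and gold standard


def simulate_phasing(truth: CallSet, flip_rate: float, seed: int) -> CallSet:
    """Swap the haplotype assignment of each het call independently.

    Homozygous and missing calls are unchanged.  With per-site flip
    probability ``p`` the expected orientation-transition (switch) rate
    between consecutive assessable sites is ``2 p (1 - p)``.
    """
    if not 0 <= flip_rate <= 0.5:
        raise ValueError("flip_rate must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    genotypes = []
    for row in truth.genotypes:
        new_row = []
        for gt in row:
            if gt.is_het() and gt.phased and rng.random() < flip_rate:
                new_row.append(Genotype(gt.b, gt.a, True))
            else:
                new_row.append(gt)
        genotypes.append(new_row)
    return truth.replace(label="phased_pred", genotypes=genotypes, metadata={})


def generate_gold(
    truth: CallSet,
    gold_sensitivity: float = 1.0,
    gold_fp_rate: float = 0.0,
    seed: int = 0,
    ref: Optional[ReferenceSequence] = None,
) -> CallSet:
    """A gold standard derived from the truth.

    With ``gold_sensitivity=1`` and ``gold_fp_rate=0`` the gold standard
    equals the truth, so concordance of a simulated caller against it has
    analytically known expectations (pct_shared -> 100 * sensitivity,
    pct_query_only -> 100 * fdr).
    """
    rng = np.random.default_rng(seed)
    include = rng.random(len(truth)) < gold_sensitivity
    keep = [i for i in range(len(truth)) if include[i]]
    gold = truth.subset(keep).replace(label="gold")
    gold.metadata = {}
    if gold_fp_rate > 0:
        if ref is None:
            raise ValueError("a reference is required to place gold false sites")
        n_fp = int(round(len(keep) * gold_fp_rate / (1 - gold_fp_rate)))
        profile = CallerProfile("gold", sensitivity=1.0, fdr=gold_fp_rate)
        fp_records, _ = _place_false_sites(truth, profile, ref, rng, n_fp)
        gold = gold.replace(
            sites=gold.sites + [r[0] for r in fp_records],
            genotypes=gold.genotypes + [r[1] for r in fp_records],
        ).sorted()
    return gold
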