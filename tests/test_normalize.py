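"""Canonicalization: left-alignment, splitting/merging, primitive decomposition."""

import itertools

import numpy as np
import pytest

import consvar as cv
from consvar.normalize import (
    decompose_primitives,
    exclude_regions,
    left_align_trim,
    merge_multiallelics,
    normalize_callset,
    select_biallelic,
    split_multiallelics,
)

from conftest import apply_variant, make_callset


def site(contig, pos, ref, alt, qual=30.0):
    alts = (alt,) if isinstance(alt, str) else tuple(alt)
    return cv.VariantSite(contig=contig, pos=pos, ref=ref, alts=alts, qual=qual)


# ---------------------------------------------------------------------------
# left_align_trim


def test_left_align_homopolymer_deletion_is_unique_leftmost(toy_ref):
    """Enumerate every (pos, ref, alt) representation of the same edit on the
    toy contig and check the normalizer returns the unique left-most minimal
    one."""
    seq = toy_ref["chr1"]  # ATTTTC
    target = apply_variant(seq, 4, "TT", "T")  # delete one T of the run
    out = left_align_trim(site("chr1", 4, "TT", "T"), toy_ref)
    assert (out.pos, out.ref, out.alts) == (1, "AT", ("A",))

    equivalents = []
    alphabet = "ACGT"
    for pos in range(1, len(seq) + 1):
        for rl in range(1, len(seq) - pos + 2):
            ref_a = seq[pos - 1 : pos - 1 + rl]
            for al in range(1, 4):
                for alt_a in map("".join, itertools.product(alphabet, repeat=al)):
                    if alt_a == ref_a:
                        continue
                    if apply_variant(seq, pos, ref_a, alt_a) == target:
                        equivalents.append((pos, ref_a, alt_a))
    assert (4, "TT", "T") in equivalents
    for pos, ref_a, alt_a in equivalents:
        norm = left_align_trim(site("chr1", pos, ref_a, alt_a), toy_ref)
        assert (norm.pos, norm.ref, norm.alts[0]) == (1, "AT", "A")
    # the result is minimal: no equivalent is shorter or more to the left
    assert min(p for p, _, _ in equivalents) == 1
    assert min(len(r) + len(a) for _, r, a in equivalents) == len("AT") + len("A")


def test_left_align_snv_and_mnp_trim(toy_ref):
    snv = site("chr2", 3, "A", "T")
    assert left_align_trim(snv, toy_ref) == snv  # already minimal

    ref = cv.ReferenceSequence({"c": "N" * 9 + "CAG" + "N" * 5})
    out = left_align_trim(site("c", 10, "CAG", "CTG"), ref)
    assert (out.pos, out.ref, out.alts) == (11, "A", ("T",))


def test_left_align_errors(toy_ref):
    with pytest.raises(ValueError, match="REF mismatch"):
        left_align_trim(site("chr1", 2, "AA", "A"), toy_ref)
    ref = cv.ReferenceSequence({"c": "TTTA"})
    with pytest.raises(ValueError, match="left-extend"):
        left_align_trim(site("c", 1, "TT", "T"), ref)


def test_left_align_idempotent_and_edit_preserving(sim_bundle):
    """Property: normalization never changes the implied edit (string-rewrite
    oracle) and is a fixed point of itself."""
    _, ref, truth, _ = sim_bundle
    rng = np.random.default_rng(5)
    runs = truth.metadata["runs"]
    picks = rng.choice(len(truth), size=200, replace=False)
    for i in picks:
        s = truth.sites[int(i)]
        out = left_align_trim(s, ref)
        assert left_align_trim(out, ref) == out
        seq = ref[s.contig]
        assert apply_variant(seq, s.pos, s.ref, s.alts[0]) == apply_variant(
            seq, out.pos, out.ref, out.alts[0]
        )


# ---------------------------------------------------------------------------
# split / merge


def test_split_multiallelics_rows_and_genotypes():
    gts = [[cv.Genotype(1, 2, True), cv.Genotype(0, 2, False), cv.Genotype(0, 0, False)]]
    cs = make_callset([("chr1", 100, "A", ("T", "G"))], samples=("a", "b", "c"), genotypes=gts)
    out = split_multiallelics(cs)
    # one row per ALT, re-sorted (alts compare lexicographically)
    assert [(s.pos, s.alts) for s in out.sites] == [(100, ("G",)), (100, ("T",))]
    row_g, row_t = out.genotypes
    # sample a carried T on hap1 and G on hap2 in the parent record
    assert row_t[0] == cv.Genotype(1, cv.OTHER_ALT, True)
    assert row_g[0] == cv.Genotype(cv.OTHER_ALT, 1, True)
    assert row_g[1] == cv.Genotype(0, 1, False)
    assert row_t[2] == cv.Genotype(0, 0, False)


def test_split_identity_on_biallelic(sim_bundle):
    _, _, truth, _ = sim_bundle
    sub = truth.subset(range(100))
    out = split_multiallelics(sub)
    assert out.keys() == sub.keys()
    assert out.genotypes == sub.genotypes


def test_merge_multiallelics_example():
    cs = make_callset([("chr1", 100, "A", "T"), ("chr1", 100, "A", "G")])
    out = merge_multiallelics(cs)
    assert len(out) == 1
    assert out.sites[0].alts == ("G", "T")  # lexicographic

    disjoint = make_callset([("chr1", 100, "A", "T"), ("chr1", 200, "C", "G")])
    assert merge_multiallelics(disjoint).keys() == disjoint.keys()


def test_split_merge_round_trip_on_random_multiallelics():
    rng = np.random.default_rng(21)
    bases = "ACGT"
    sites = []
    for i in range(200):
        pos = 10 + i * 10
        ref = bases[rng.integers(4)]
        n_alt = int(rng.integers(1, 4))
        alts = tuple(rng.permutation([b for b in bases if b != ref])[:n_alt])
        sites.append(("chr1", pos, ref, alts))
    cs = make_callset(sites)
    merged = merge_multiallelics(split_multiallelics(cs))
    original = {(s.contig, s.pos, s.ref, frozenset(s.alts)) for s in cs.sites}
    recovered = {(s.contig, s.pos, s.ref, frozenset(s.alts)) for s in merged.sites}
    assert recovered == original


def test_merge_resolves_qual_filters_info(caplog):
    a = site("chr1", 50, "A", "T", qual=10.0).with_(
        filters=frozenset({"X"}), info={"DP": 5.0, "MQ": 30.0}
    )
    b = site("chr1", 50, "A", "G", qual=99.0).with_(
        filters=frozenset({"Y"}), info={"DP": 5.0, "MQ": 60.0}
    )
    cs = cv.CallSet(
        label="m", samples=["s"], sites=[a, b],
        genotypes=[[cv.Genotype(0, 1, False)], [cv.Genotype(0, 0, False)]],
    )
    with caplog.at_level("WARNING"):
        out = merge_multiallelics(cs)
    m = out.sites[0]
    assert m.qual == 99.0
    assert m.filters == frozenset({"X", "Y"})
    assert m.info == {"DP": 5.0}  # conflicting MQ dropped
    assert any("dropping INFO" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# decompose_primitives


def test_decompose_mnp_into_snvs():
    children = decompose_primitives(site("chr1", 100, "AC", "TG"))
    assert [(c.pos, c.ref, c.alts[0]) for c in children] == [(100, "A", "T"), (101, "C", "G")]


def test_decompose_passthrough_and_trim():
    s = site("chr1", 100, "A", "T")
    assert decompose_primitives(s) == [s]
    children = decompose_primitives(site("chr1", 100, "ATG", "ATC"))
    assert [(c.pos, c.ref, c.alts[0]) for c in children] == [(102, "G", "C")]


@pytest.mark.parametrize(
    "ref_a,alt_a",
    [("ACGT", "TG"), ("AC", "TGCA"), ("ACGTA", "AGT"), ("CCGA", "TTGAA")],
)
def test_decompose_complex_conserves_haplotype(ref_a, alt_a):
    """Applying all children jointly must reproduce the parent edit."""
    parent = site("chr1", 11, ref_a, alt_a)
    seq = "N" * 10 + ref_a + "N" * 10
    target = apply_variant(seq, parent.pos, ref_a, alt_a)
    children = decompose_primitives(parent)
    for c in children:
        assert c.is_biallelic
    # apply right-to-left so positions stay valid; at the anchor column the
    # INDEL (longer REF span) goes before the SNV sharing its position
    out = seq
    for c in sorted(children, key=lambda c: (-c.pos, -len(c.ref), -len(c.alts[0]))):
        out = apply_variant(out, c.pos, c.ref, c.alts[0])
    assert out == target


def test_decompose_mismatch_count_conserved():
    rng = np.random.default_rng(3)
    bases = "ACGT"
    for _ in range(50):
        k = int(rng.integers(2, 6))
        ref_a = "".join(rng.choice(list(bases), size=k))
        alt_a = "".join(rng.choice(list(bases), size=k))
        if ref_a == alt_a:
            continue
        n_mismatch = sum(1 for r, a in zip(ref_a, alt_a) if r != a)
        children = decompose_primitives(site("chr1", 50, ref_a, alt_a))
        assert len(children) == n_mismatch


# ---------------------------------------------------------------------------
# selection and region exclusion


def test_select_biallelic_counts():
    cs = make_callset([("chr1", 10, "A", "T"), ("chr1", 20, "C", ("G", "T"))])
    kept = select_biallelic(cs)
    assert len(kept) == 1 and len(cs) - len(kept) == 1


def test_exclude_regions_rules():
    cs = make_callset(
        [
            ("chr1", 100, "A", "T"),
            ("chrY", 500, "C", "G"),
            ("chrX", 50, "G", "A"),
            ("chrX", 900, "G", "A"),
        ],
        contigs=["chr1", "chrX", "chrY"],
    )
    par = cv.RegionSet({"chrX": [(0, 100)]}, "par")
    out = exclude_regions(cs, exclusions=None, par=par)
    assert [(s.contig, s.pos) for s in out.sites] == [("chr1", 100), ("chrX", 50)]


def test_exclude_regions_matches_brute_force(sim_bundle):
    cfg, ref, truth, regions = sim_bundle
    out = exclude_regions(truth, exclusions=regions["exclusion"], par=regions["par"])
    expected = []
    for s in truth.sites:
        if regions["exclusion"].contains(s.contig, s.pos):
            continue
        if s.contig == "chrY":
            continue
        if s.contig == "chrX" and not regions["par"].contains(s.contig, s.pos):
            continue
        expected.append(s.key())
    assert out.keys() == expected


# ---------------------------------------------------------------------------
# full chain


def test_normalize_callset_chain(toy_ref):
    ref = cv.ReferenceSequence({"c": "ATTTTCAGGTACGT"})
    cs = make_callset(
        [
            ("c", 4, "TT", "T"),       # un-left-aligned deletion
            ("c", 8, "GG", "CA"),      # MNP
            ("c", 12, "C", "G"),       # plain SNV
        ],
        contigs=["c"],
    )
    out = normalize_callset(cs, ref)
    assert [(s.pos, s.ref, s.alts[0]) for s in out.sites] == [
        (1, "AT", "A"),
        (8, "G", "C"),
        (9, "G", "A"),
        (12, "C", "G"),
    ]


def test_normalize_callset_idempotent_and_unique(sim_bundle):
    cfg, ref, truth, _ = sim_bundle
    prof = cv.CallerProfile("x", sensitivity=0.9, fdr=0.05,
                            representation_style="right_shifted")
    cs = cv.simulate_caller(truth, prof, ref, seed=17)
    once = normalize_callset(cs, ref)
    twice = normalize_callset(once, ref)
    assert twice.keys() == once.keys()
    assert len(set(once.keys())) == len(once)  # unique by SiteKey


def test_normalize_deduplicates_identical_records(toy_ref):
    cs = make_callset([("chr1", 2, "T", "A", 10.0), ("chr1", 2, "T", "A", 99.0)])
    out = normalize_callset(cs, toy_ref)
    assert len(out) == 1
    assert out.sites[0].qual == 99.0  # highest-QUAL record wins


def test_end_to_end_identity_all_styles(sim_bundle):
    """A perfect caller (sensitivity 1, no false calls) must normalize back
    to exactly the truth site-key set, whatever representation it emits."""
    cfg, ref, truth, _ = sim_bundle
    for style in ("canonical", "right_shifted", "mnp_joined", "multiallelic_merged"):
        prof = cv.CallerProfile("p", sensitivity=1.0, fdr=0.0, representation_style=style)
        cs = cv.simulate_caller(truth, prof, ref, seed=23)
        assert normalize_callset(cs, ref).key_set() == truth.key_set(), style
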