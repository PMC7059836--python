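import numpy as np
import pytest

import consvar as cv


@pytest.fixture(scope="session")
def sim_cfg() -> cv.SimulationConfig:
    return cv.SimulationConfig(seed=7, n_sites=2000, n_samples=8)


@pytest.fixture(scope="session")
def sim_bundle(sim_cfg):
    """One shared synthetic study: (cfg, reference, phased truth, region bundle)."""
    ref, truth, regions = cv.generate_truth(sim_cfg)
    return sim_cfg, ref, truth, regions


@pytest.fixture()
def toy_ref() -> cv.ReferenceSequence:
    return cv.ReferenceSequence(
        {
            "chr1": "ATTTTC",
            "chr2": "GGACAGTTTACC" * 4,
        }
    )


def make_callset(
    sites,
    label="test",
    samples=("S0",),
    genotypes=None,
    contigs=None,
):
    """Build a CallSet from (contig, pos, ref, alt_or_alts[, qual]) tuples."""
    vsites = []
    for t in sites:
        contig, pos, ref, alt = t[:4]
        qual = t[4] if len(t) > 4 else 30.0
        alts = (alt,) if isinstance(alt, str) else tuple(alt)
        vsites.append(cv.VariantSite(contig=contig, pos=pos, ref=ref, alts=alts, qual=qual))
    if genotypes is None:
        genotypes = [[cv.Genotype(0, 1, False)] * len(samples) for _ in vsites]
    return cv.CallSet(
        label=label,
        samples=list(samples),
        sites=vsites,
        genotypes=genotypes,
        contigs=list(contigs) if contigs else [],
    )


def apply_variant(seq: str, pos: int, ref: str, alt: str) -> str:
    """String-rewrite oracle: the contig after applying a (pos, ref, alt) edit."""
    assert seq[pos - 1 : pos - 1 + len(ref)] == ref
    return seq[: pos - 1] + alt + seq[pos - 1 + len(ref) :]


def binom_interval_99(n: int, p: float) -> tuple[int, int]:
    from scipy.stats import binom

    return int(binom.ppf(0.005, n, p)), int(binom.ppf(0.995, n, p))


def switch_count_interval_99(n_pairs: int, p_flip: float) -> tuple[float, float]:
    """99% interval for the switch count over overlapping consecutive pairs.

    With i.i.d. per-site flips at rate p, each transition is Bernoulli
    q = 2p(1-p), but adjacent transitions share a flip, so
    Var = n q(1-q) + 2(n-1) (p(1-p) - q^2) -- roughly twice the binomial
    variance.  Normal approximation at z = 2.576.
    """
    q = 2 * p_flip * (1 - p_flip)
    cov = p_flip * (1 - p_flip) - q * q
    var = n_pairs * q * (1 - q) + 2 * max(n_pairs - 1, 0) * cov
    mean = n_pairs * q
    half = 2.576 * float(np.sqrt(var))
    return mean - half, mean + half
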