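"""Exact mutation-drift equilibrium for a line of two diploid individuals.

Each segregating mutation is followed as an absorbing Markov chain over the
seven two-sib genotype configurations (the SFS elements), with absorption at
loss (0 alt copies) and fixation (4 alt copies).  Under neutrality and
infinite sites every mutation evolves independently, so the chain's
fundamental matrix gives the exact expected SFS: the expected number of
segregating sites in element *i* at equilibrium is (influx per generation)
x (expected generations a mutation spends in state *i* before absorption).

Two offspring models are provided:

``sib_mating``
    Strict brother-sister mating: each offspring receives one allele from
    parent A and one from parent B (independent Mendelian draws).

``wf_selfing``
    Wright-Fisher with N = 2 and selfing permitted: each of an offspring's
    two alleles is an independent draw from the parental allele pool, alt
    with probability q = (g_A + g_B)/4.

The two models have different equilibria (mean mutation lifetimes 107/29
and 29/6 generations respectively); both are exposed and a caller must
choose explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .sfs import COPIES_TO_ELEMENT, ELEMENT_COPIES, ELEMENTS, FIXATION, LOSS, SFSVector

MATING_MODELS = ("sib_mating", "wf_selfing")

#: default per-site per-generation reference mutation rate (the rate the
#: expected SFS is computed at; estimates are expressed in multiples of it)
REFERENCE_RATE = 1e-8


@dataclass(frozen=True)
class MarkovSFSModel:
    """Absorbing-chain transition structure over the 7 transient SFS states.

    ``Q`` is the 7x7 transient block (element order as in :data:`ELEMENTS`),
    ``R`` the 7x2 block into (loss, fixation).  ``start_distribution`` is
    the state distribution of a brand-new mutation: probability 1/2 on each
    single-heterozygote state, because a mutation arises in one gamete of
    one of the two next-generation individuals.
    """

    mating: str
    Q: np.ndarray
    R: np.ndarray
    start_distribution: np.ndarray


def offspring_genotype_distribution(mating: str, g_a: int, g_b: int) -> np.ndarray:
    """P(offspring carries 0, 1, 2 alt copies) given parental alt counts."""
    if mating == "wf_selfing":
        q = (g_a + g_b) / 4.0
        return np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])
    if mating == "sib_mating":
        pa, pb = g_a / 2.0, g_b / 2.0
        return np.array([(1 - pa) * (1 - pb), pa * (1 - pb) + (1 - pa) * pb, pa * pb])
    raise ConfigError(f"unknown mating model {mating!r}; expected one of {MATING_MODELS}")


def build_markov_model(mating: str) -> MarkovSFSModel:
    """Build the genotype-pair chain for one mutation under a mating model.

    The next generation consists of two offspring of the current pair,
    drawn independently; the ordered offspring pair (a', b') is classified
    into an SFS element or an absorbing state by its alt-copy counts.
    """
    n = len(ELEMENTS)
    Q = np.zeros((n, n))
    R = np.zeros((n, 2))
    for i, element in enumerate(ELEMENTS):
        g_a, g_b = ELEMENT_COPIES[element]
        p = offspring_genotype_distribution(mating, g_a, g_b)
        for a in range(3):
            for b in range(3):
                pr = p[a] * p[b]
                if (a, b) == LOSS:
                    R[i, 0] += pr
                elif (a, b) == FIXATION:
                    R[i, 1] += pr
                else:
                    Q[i, ELEMENTS.index(COPIES_TO_ELEMENT[(a, b)])] += pr
    start = np.zeros(n)
    start[ELEMENTS.index("RARR")] = 0.5
    start[ELEMENTS.index("RRRA")] = 0.5
    return MarkovSFSModel(mating=mating, Q=Q, R=R, start_distribution=start)


def expected_sfs(model: MarkovSFSModel) -> tuple[SFSVector, SFSVector, float]:
    """Exact equilibrium SFS from the fundamental matrix.

    Returns ``(sojourn, proportions, mean_lifetime)`` where ``sojourn[i]``
    is the expected number of generations one new mutation spends in
    element *i* before absorption, ``proportions`` is the sojourn vector
    normalised to sum one (the equilibrium SFS shape), and
    ``mean_lifetime`` is the total expected number of segregating
    generations per mutation.
    """
    n = len(ELEMENTS)
    m = np.eye(n) - model.Q
    # absorption is certain (spectral radius of Q < 1), so I - Q is regular
    assert np.max(np.abs(np.linalg.eigvals(model.Q))) < 1.0
    sojourn = np.linalg.solve(m.T, model.start_distribution)
    lifetime = float(sojourn.sum())
    return SFSVector(sojourn), SFSVector(sojourn / lifetime), lifetime


def expected_segregating_sites(model: MarkovSFSModel, mu: float, L: float) -> float:
    """Expected segregating-site count at equilibrium: influx x lifetime.

    Mutations enter at rate 4*L*mu per generation (four haploid genomes,
    each site mutating at ``mu``), and each segregates for
    ``mean_lifetime`` generations on average.
    """
    if mu < 0 or L < 0:
        raise ValueError("mu and L must be non-negative")
    _, _, lifetime = expected_sfs(model)
    return 4.0 * L * mu * lifetime


def expected_sfs_counts_at(model: MarkovSFSModel, mu: float, L: float) -> SFSVector:
    """Expected per-element segregating-site counts at equilibrium."""
    if mu < 0 or L < 0:
        raise ValueError("mu and L must be non-negative")
    sojourn, _, _ = expected_sfs(model)
    return SFSVector(4.0 * L * mu * sojourn.counts)


@dataclass(frozen=True)
class EffectiveSizeConstants:
    """Asymptotic heterozygosity-decay constants for strict full-sib lines."""

    lambda_fs: float
    Ne_full_sib: float


def full_sib_effective_size() -> EffectiveSizeConstants:
    """Effective size of a line maintained by strict brother-sister mating.

    Heterozygosity under full-sib mating obeys H_t = H_{t-1}/2 + H_{t-2}/4;
    the dominant root lambda = (1+sqrt(5))/4 of its companion matrix is the
    asymptotic per-generation retention, and equating it to the Wright-Fisher
    decay 1 - 1/(2*Ne) gives Ne = 1/(2*(1-lambda)) ~ 2.6.
    """
    companion = np.array([[0.5, 0.25], [1.0, 0.0]])
    lam = float(np.max(np.linalg.eigvals(companion).real))
    return EffectiveSizeConstants(lambda_fs=lam, Ne_full_sib=1.0 / (2.0 * (1.0 - lam)))


def watterson_expected_diversity(mu: float, Ne: float, L: float) -> float:
    """Equilibrium diversity expectation 4*mu*Ne*L (expected variant count)."""
    if mu < 0 or Ne < 0 or L < 0:
        raise ValueError("all arguments must be non-negative")
    return 4.0 * mu * Ne * L


# ---------------------------------------------------------------------------
# Lumped 4-class solve.  The chain is symmetric under exchanging the A/B
# labels, so the symmetric state pairs can be merged exactly.  This solve is
# written from the class-level offspring distributions directly (not from the
# 7-state matrix) and serves as an independent cross-check of the full solve;
# the full 7-state solve is authoritative.
# ---------------------------------------------------------------------------

LUMPED_CLASSES = ("single_het", "double_het", "single_hom", "het_hom")
_CLASS_REP = {"single_het": (1, 0), "double_het": (1, 1), "single_hom": (2, 0), "het_hom": (2, 1)}
_CLASS_OF_ELEMENT = {
    "RARR": "single_het", "RRRA": "single_het",
    "RARA": "double_het",
    "AARR": "single_hom", "RRAA": "single_hom",
    "AARA": "het_hom", "RAAA": "het_hom",
}


def lumped_expected_classes(mating: str) -> tuple[dict[str, float], float]:
    """Sojourn times per lumped symmetry class and the mean lifetime.

    Classes: single heterozygote (RARR+RRRA), double heterozygote (RARA),
    single homozygote-alt (AARR+RRAA), heterozygote+homozygote (AARA+RAAA).
    """
    n = len(LUMPED_CLASSES)
    T = np.zeros((n, n))
    for i, cls in enumerate(LUMPED_CLASSES):
        p0, p1, p2 = offspring_genotype_distribution(mating, *_CLASS_REP[cls])
        T[i, LUMPED_CLASSES.index("single_het")] = 2 * p1 * p0
        T[i, LUMPED_CLASSES.index("double_het")] = p1 * p1
        T[i, LUMPED_CLASSES.index("single_hom")] = 2 * p2 * p0
        T[i, LUMPED_CLASSES.index("het_hom")] = 2 * p2 * p1
    start = np.array([1.0, 0.0, 0.0, 0.0])  # a new mutation is a single het
    sojourn = np.linalg.solve((np.eye(n) - T).T, start)
    return dict(zip(LUMPED_CLASSES, sojourn)), float(sojourn.sum())


def lump_sfs_vector(v: SFSVector) -> dict[str, float]:
    """Aggregate a 7-element SFS into the 4 symmetry classes."""
    out = {c: 0.0 for c in LUMPED_CLASSES}
    for e in ELEMENTS:
        out[_CLASS_OF_ELEMENT[e]] += v[e]
    return out
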