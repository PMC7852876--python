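"""Forward-in-time simulation of segregating variation in a two-sib line.

The default engine is event-based: each segregating mutation is an
independent realisation of the genotype-pair chain of
:mod:`sibline.equilibrium`, which is exact under neutrality and infinite
sites because the marginal per-site dynamics do not depend on linkage.
New mutations enter each generation as a Poisson(4*L*mu) influx (four
haploid genomes mutating at rate mu per site), each starting as a single
heterozygote in one of the two individuals with equal probability.  The
per-adjacent-site recombination rate is accepted for interface parity and
has no effect in this mode; a literal genome-array engine (with linkage and
recombination) is provided for validation at small L.

An ensemble of replicate trajectories, each started from a monomorphic
population and run for a fixed number of generations, yields the expected
SFS, its Monte-Carlo precision, and the generation by which the SFS shape
has equilibrated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .equilibrium import build_markov_model
from .errors import ConfigError
from .sfs import ELEMENTS, SFSVector

logger = logging.getLogger(__name__)

_N_EL = len(ELEMENTS)
_RARR = ELEMENTS.index("RARR")
_RRRA = ELEMENTS.index("RRRA")


@dataclass(frozen=True)
class SimParams:
    """Simulation configuration.

    ``L_per_chromosome`` are callable-site counts; only their sum matters to
    the event-based engine.  Defaults mirror the reference experiment: a
    two-individual line, mu = 1e-8 per site per generation, recombination
    5e-9 between adjacent sites, 100 generations, 1000 replicates.
    """

    L_per_chromosome: tuple[int, ...] = (2_725_521_370,)
    mu: float = 1e-8
    recomb: float = 5e-9
    generations: int = 100
    replicates: int = 1000
    mating: str = "wf_selfing"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(L < 0 for L in self.L_per_chromosome):
            raise ConfigError("chromosome sizes must be non-negative")
        if self.generations < 1 or self.replicates < 1:
            raise ConfigError("generations and replicates must be >= 1")
        if self.mu < 0 or self.recomb < 0:
            raise ConfigError("rates must be non-negative")

    @property
    def total_L(self) -> int:
        return int(sum(self.L_per_chromosome))


@dataclass
class ReplicateTrajectory:
    """Per-generation segregating-site counts by SFS element for one replicate."""

    counts: np.ndarray  # (generations, 7) integer counts; row g is generation g+1

    @property
    def generations(self) -> int:
        return self.counts.shape[0]

    def sfs_at(self, generation: int) -> SFSVector:
        """SFS at a 1-based generation index."""
        return SFSVector(self.counts[generation - 1].astype(float))

    @property
    def final_sfs(self) -> SFSVector:
        return self.sfs_at(self.generations)


@dataclass
class EnsembleSummary:
    params: SimParams
    mean_counts: SFSVector
    mean_proportions: SFSVector
    #: per-element standard error of the mean of final-generation proportions
    #: across replicates; None when replicates == 1
    sem_proportions: np.ndarray | None
    #: (generations, 7) mean of per-replicate proportions, per generation
    per_generation_mean_proportions: np.ndarray
    n_replicates: int
    #: replicates with zero segregating sites at the final generation
    #: (excluded from proportion averaging)
    n_excluded: int
    #: (replicates, 7) final-generation counts, kept for resampling checks
    final_counts: np.ndarray = field(repr=False, default=None)


def replicate_rng(master_seed: int, replicate: int) -> np.random.Generator:
    """Stable, documented per-replicate stream: SeedSequence(master, spawn_key=(r,))."""
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(master_seed, spawn_key=(replicate,))))


def simulate_replicate(
    params: SimParams,
    replicate_seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ReplicateTrajectory:
    """One trajectory: monomorphic start, then ``generations`` rounds of
    mutation influx and genotype-pair transitions.

    Per generation the next pair of individuals is formed: every extant
    mutation advances one chain step (mutations hitting loss or fixation
    leave the segregating tally) and Poisson(4*L*mu) new mutations enter at
    the start state.  Lineages are tracked as per-state counts, which is
    sufficient because they are exchangeable.
    """
    if rng is None:
        rng = np.random.default_rng(replicate_seed if replicate_seed is not None else params.seed)
    model = build_markov_model(params.mating)
    # transition rows over 9 outcomes: 7 transient elements, loss, fixation
    P = np.hstack([model.Q, model.R])
    influx = 4.0 * params.total_L * params.mu
    counts = np.zeros(_N_EL, dtype=np.int64)
    out = np.zeros((params.generations, _N_EL), dtype=np.int64)
    for g in range(params.generations):
        nxt = np.zeros(9, dtype=np.int64)
        for s in range(_N_EL):
            if counts[s]:
                nxt += rng.multinomial(counts[s], P[s])
        counts = nxt[:_N_EL]
        n_new = rng.poisson(influx)
        in_a = rng.binomial(n_new, 0.5)
        counts[_RARR] += in_a
        counts[_RRRA] += n_new - in_a
        out[g] = counts
    return ReplicateTrajectory(counts=out)


def run_ensemble(params: SimParams) -> EnsembleSummary:
    """Run ``params.replicates`` independent trajectories and summarise.

    Mean proportions are the across-replicate average of per-replicate
    proportions (the estimand whose precision the per-element SEM
    describes); replicates with no segregating sites at a generation are
    excluded from that generation's proportion average.
    """
    G, R = params.generations, params.replicates
    all_counts = np.empty((R, G, _N_EL), dtype=np.int64)
    for r in range(R):
        traj = simulate_replicate(params, rng=replicate_rng(params.seed, r))
        all_counts[r] = traj.counts

    final = all_counts[:, -1, :].astype(float)
    totals = final.sum(axis=1)
    nonzero = totals > 0
    n_excluded = int(R - nonzero.sum())
    if n_excluded:
        logger.info("run_ensemble: %d replicate(s) had no segregating sites at the final generation", n_excluded)
    mean_counts = SFSVector(final.mean(axis=0))

    if nonzero.any():
        props = final[nonzero] / totals[nonzero, None]
        mean_props = props.mean(axis=0)
    else:
        mean_props = np.zeros(_N_EL)
    if R > 1 and nonzero.sum() > 1:
        sem = props.std(axis=0, ddof=1) / np.sqrt(nonzero.sum())
    else:
        sem = None

    per_gen = np.full((G, _N_EL), np.nan)
    gen_counts = all_counts.astype(float)
    gen_totals = gen_counts.sum(axis=2)  # (R, G)
    for g in range(G):
        ok = gen_totals[:, g] > 0
        if ok.any():
            per_gen[g] = (gen_counts[ok, g, :] / gen_totals[ok, g, None]).mean(axis=0)

    return EnsembleSummary(
        params=params,
        mean_counts=mean_counts,
        mean_proportions=SFSVector(mean_props) if mean_props.sum() > 0 else SFSVector.zeros(),
        sem_proportions=sem,
        per_generation_mean_proportions=per_gen,
        n_replicates=R,
        n_excluded=n_excluded,
        final_counts=all_counts[:, -1, :].copy(),
    )


def equilibration_generation(summary: EnsembleSummary, tol: float = 0.02) -> int:
    """Smallest 1-based generation g such that every element's mean
    proportion stays within ``tol`` (absolute) of its final-generation value
    for all generations >= g.  Generations with no segregating sites in any
    replicate (NaN rows) count as unstable.
    """
    per_gen = summary.per_generation_mean_proportions
    final = per_gen[-1]
    if np.any(np.isnan(final)):
        logger.warning("equilibration_generation: final generation has no data; returning final generation")
        return per_gen.shape[0]
    dev = np.abs(per_gen - final)
    unstable = np.any(dev > tol, axis=1) | np.any(np.isnan(per_gen), axis=1)
    if not unstable.any():
        return 1
    last_bad = int(np.nonzero(unstable)[0][-1])  # 0-based row -> generation last_bad+1
    g = last_bad + 2
    if g > per_gen.shape[0]:
        logger.warning("equilibration_generation: tolerance never satisfied before the final generation")
        return per_gen.shape[0]
    return g


def expected_sfs_counts(summary: EnsembleSummary) -> SFSVector:
    """The expected SFS u: mean per-element counts at the final generation."""
    return summary.mean_counts


# ---------------------------------------------------------------------------
# Literal genome-array engine (validation only).  Simulates the four
# haplotypes explicitly with recombination and linkage; feasible for small L.
# ---------------------------------------------------------------------------


def _gamete(rng: np.random.Generator, haplotypes: np.ndarray, recomb: float) -> np.ndarray:
    """Recombined gamete from one diploid parent (pair of haplotype arrays)."""
    L = haplotypes.shape[1]
    n_cuts = rng.poisson(recomb * max(L - 1, 0))
    which = np.zeros(L, dtype=np.int64)
    if n_cuts:
        cuts = rng.integers(1, L, size=n_cuts)
        np.add.at(which, cuts, 1)
    parity = (rng.integers(2) + np.cumsum(which)) % 2
    return np.where(parity == 0, haplotypes[0], haplotypes[1]).astype(bool)


def simulate_genome_array(
    L: int,
    mu: float,
    recomb: float,
    generations: int,
    mating: str = "wf_selfing",
    rng: np.random.Generator | None = None,
) -> SFSVector:
    """Per-site diploid-genome simulation; returns the final-generation SFS.

    Used to validate the event-based engine: with linkage and recombination
    modelled literally, the SFS proportions must be statistically
    indistinguishable from the lineage engine's.
    """
    if mating not in ("wf_selfing", "sib_mating"):
        raise ConfigError(f"unknown mating model {mating!r}")
    rng = rng or np.random.default_rng()
    # genomes[individual, haplotype, site]
    genomes = np.zeros((2, 2, L), dtype=bool)
    for _ in range(generations):
        new = np.zeros_like(genomes)
        for child in range(2):
            for h in range(2):
                if mating == "sib_mating":
                    parent = h  # one gamete from each parent
                else:
                    parent = rng.integers(2)
                gam = _gamete(rng, genomes[parent], recomb)
                n_mut = rng.poisson(L * mu)
                if n_mut:
                    gam = gam.copy()
                    gam[rng.integers(0, L, size=n_mut)] = True
                new[child, h] = gam
        genomes = new
    a = genomes[0].sum(axis=0)
    b = genomes[1].sum(axis=0)
    code = 3 * a + b  # 0..8
    tally = np.bincount(code, minlength=9)
    from .sfs import COPIES_TO_ELEMENT

    counts = {}
    for (ga, gb), element in COPIES_TO_ELEMENT.items():
        counts[element] = int(tally[3 * ga + gb])
    return SFSVector.from_dict(counts)


# ---------------------------------------------------------------------------
# TSV export
# ---------------------------------------------------------------------------


def write_ensemble_tsv(summary: EnsembleSummary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("element\tmean_count\tmean_proportion\tsem_proportion\n")
        sem = summary.sem_proportions
        for i, e in enumerate(ELEMENTS):
            s = f"{sem[i]:.6g}" if sem is not None else "NA"
            fh.write(f"{e}\t{summary.mean_counts.counts[i]:.6g}\t{summary.mean_proportions.counts[i]:.6g}\t{s}\n")


def write_per_generation_tsv(summary: EnsembleSummary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("generation\t" + "\t".join(ELEMENTS) + "\n")
        for g, row in enumerate(summary.per_generation_mean_proportions, start=1):
            fh.write(f"{g}\t" + "\t".join(f"{x:.6g}" for x in row) + "\n")
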