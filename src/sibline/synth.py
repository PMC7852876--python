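"""Synthetic joint multi-sample VCFs with known ground truth.

The generator emulates the structure of the study design being modelled:
four inbred strains sampled as focal pairs (two individuals each), plus
twelve wild-mouse "bait" genomes, joint-genotyped over a callable genome of
L sites.  Per strain, true segregating variants are drawn from the
equilibrium two-sib SFS at a configured mutation rate (Poisson total with
mean 4*L*mu*mean_lifetime, elements multinomial on the exact equilibrium
proportions); every other sample is homozygous reference.  Labelled
artifact classes are injected alongside:

``paralog_cluster``   runs of 3-8 double-heterozygote sites in a short
                      span with elevated focal depth and a shared phase
                      set -- the signature of misaligned paralogous reads
``bait_impurity``     a variant-like site whose bait samples carry 2 alt
                      reads (fails the bait purity criterion)
``low_qual``          QUAL below the quality threshold
``low_depth``         one inbred sample below the depth threshold
``multiallelic``      three alleles segregating (focal A carries alt1,
                      focal B alt2)
``indel``             an insertion rather than an SNV

True variants are drawn from the *callable* genome -- sites that pass the
quality, depth and purity criteria by definition -- so their QUAL, depths
and allele balances are sampled conditional on passing those thresholds;
the artifact classes supply the failures.  Positions keep a minimum
spacing (default 200 bp) so that the phase-proximity filter's window never
spans two independent sites: at the genome scale being emulated (hundreds
of variants over gigabases) chance proximity is vanishingly rare, and the
reduced test-scale genome would otherwise misrepresent it.

Emitting gigabases of non-variant records is infeasible, so callable-site
counts are written as a compact per-chromosome sidecar TSV; an all-sites
mode (practical for L <= 1e5) additionally emits every non-variant record
so the literal callable-site counter can be exercised.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .equilibrium import build_markov_model, expected_sfs, expected_segregating_sites
from .errors import ConfigError, InputError
from .filtering import CallableSiteTally, SampleRoleMap
from .sfs import ELEMENT_COPIES, ELEMENTS

logger = logging.getLogger(__name__)

ARTIFACT_CLASSES = ("paralog_cluster", "bait_impurity", "low_qual", "low_depth", "multiallelic", "indel")

#: the filter criterion each artifact class is designed to fail
ARTIFACT_EXPECTED_CRITERIA = {
    "paralog_cluster": ("c8", "c9"),
    "bait_impurity": ("c3",),
    "low_qual": ("c1",),
    "low_depth": ("c2",),
    "multiallelic": ("c10",),
    "indel": ("c6",),
}

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class StrainSpec:
    name: str
    mu: float  # true per-site per-generation rate
    sample_a: str
    sample_b: str


@dataclass(frozen=True)
class ArtifactRates:
    """Per-callable-site artifact probabilities (clusters per start site)."""

    paralog_cluster: float = 5e-6
    bait_impurity: float = 5e-6
    low_qual: float = 5e-6
    low_depth: float = 5e-6
    multiallelic: float = 2e-6
    indel: float = 3e-6
    cluster_size: tuple[int, int] = (3, 8)
    cluster_span: int = 80  # bp

    def __post_init__(self) -> None:
        for name in ("paralog_cluster", "bait_impurity", "low_qual", "low_depth", "multiallelic", "indel"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"artifact rate {name} must be in [0, 1]")

    @classmethod
    def none(cls) -> "ArtifactRates":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class DepthModel:
    """Negative-binomial per-sample read depth (mean coverage ~30x)."""

    mean: float = 30.0
    size: float = 10.0  # NB shape; variance = mean + mean^2/size

    def draw(self, rng: np.random.Generator, n: int, minimum: int = 1,
             maximum: int | None = None) -> np.ndarray:
        """NB draws conditioned on [minimum, maximum].

        Callable sites have DP >= the depth threshold by definition, and lie
        outside collapsed-repeat regions (whose hallmark is depth beyond
        twice the genomic mean), so callable-site depths are drawn truncated.
        """
        p = self.size / (self.size + self.mean)
        out = rng.negative_binomial(self.size, p, size=n)
        def bad(x):
            b = x < minimum
            if maximum is not None:
                b |= x > maximum
            return b
        while np.any(bad(out)):
            b = bad(out)
            out[b] = rng.negative_binomial(self.size, p, size=int(b.sum()))
        return out

    @property
    def callable_cap(self) -> int:
        """Per-sample depth ceiling at callable sites (< 2x mean with margin)."""
        return int(1.8 * self.mean)


@dataclass
class SyntheticConfig:
    """Generator configuration; defaults are the reduced test-scale genome
    (1 Mb over two chromosomes, mu scaled up to 1e-5 so variant counts land
    in the low hundreds, mirroring the genome-scale regime)."""

    strains: tuple[StrainSpec, ...] = (
        StrainSpec("C3H", 1e-5, "C3H_A", "C3H_B"),
        StrainSpec("BL6", 1e-5, "BL6_A", "BL6_B"),
        StrainSpec("BALBc", 1e-5, "BALBc_A", "BALBc_B"),
        StrainSpec("FVB", 1e-5, "FVB_A", "FVB_B"),
    )
    n_bait: int = 12
    n_other_inbred: int = 0
    chromosomes: dict[str, int] = field(default_factory=lambda: {"chr1": 500_000, "chr2": 500_000})
    mating: str = "wf_selfing"
    artifacts: ArtifactRates = field(default_factory=ArtifactRates)
    depth: DepthModel = field(default_factory=DepthModel)
    qual_range: tuple[float, float] = (200.0, 2000.0)
    min_site_spacing: int = 200  # bp between independently placed sites
    min_dp: int = 10  # callable-depth floor for inbred samples
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.strains:
            raise ConfigError("at least one strain required")
        if any(L < 1 for L in self.chromosomes.values()):
            raise ConfigError("chromosome lengths must be >= 1")

    @property
    def total_L(self) -> int:
        return int(sum(self.chromosomes.values()))

    def roles(self) -> SampleRoleMap:
        return SampleRoleMap(
            strains={s.name: (s.sample_a, s.sample_b) for s in self.strains},
            other_inbred=tuple(f"OTH_{i+1:02d}" for i in range(self.n_other_inbred)),
            bait=tuple(f"WILD_{i+1:02d}" for i in range(self.n_bait)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        kwargs = dict(data)
        if "strains" in kwargs:
            kwargs["strains"] = tuple(
                StrainSpec(s["name"], float(s["mu"]), s.get("sample_a", f"{s['name']}_A"), s.get("sample_b", f"{s['name']}_B"))
                for s in kwargs["strains"]
            )
        if "artifacts" in kwargs:
            art = dict(kwargs["artifacts"])
            if "cluster_size" in art:
                art["cluster_size"] = tuple(art["cluster_size"])
            kwargs["artifacts"] = ArtifactRates(**art)
        if "depth" in kwargs:
            kwargs["depth"] = DepthModel(**kwargs["depth"])
        if "qual_range" in kwargs:
            kwargs["qual_range"] = tuple(kwargs["qual_range"])
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from None

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "strains": [
                {"name": s.name, "mu": s.mu, "sample_a": s.sample_a, "sample_b": s.sample_b}
                for s in self.strains
            ],
            "n_bait": self.n_bait,
            "n_other_inbred": self.n_other_inbred,
            "chromosomes": dict(self.chromosomes),
            "mating": self.mating,
            "artifacts": {
                k: getattr(self.artifacts, k)
                for k in ("paralog_cluster", "bait_impurity", "low_qual", "low_depth", "multiallelic", "indel")
            }
            | {"cluster_size": list(self.artifacts.cluster_size), "cluster_span": self.artifacts.cluster_span},
            "depth": {"mean": self.depth.mean, "size": self.depth.size},
            "qual_range": list(self.qual_range),
            "min_site_spacing": self.min_site_spacing,
            "min_dp": self.min_dp,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class TruthRecord:
    chrom: str
    pos: int
    strain: str | None
    klass: str  # "true_variant" or an artifact class
    element: str | None = None  # SFS element for true variants
    cluster_id: int | None = None  # shared by sites of one paralog cluster


# ---------------------------------------------------------------------------
# position placement
# ---------------------------------------------------------------------------


class _Placer:
    """Uniform placement over the genome with a minimum pairwise spacing."""

    def __init__(self, chromosomes: dict[str, int], spacing: int, rng: np.random.Generator):
        self.chroms = list(chromosomes)
        self.lengths = np.array([chromosomes[c] for c in self.chroms], dtype=float)
        self.weights = self.lengths / self.lengths.sum()
        self.spacing = spacing
        self.rng = rng
        self.placed: dict[str, list[int]] = {c: [] for c in self.chroms}

    def _free(self, chrom: str, lo: int, hi: int) -> bool:
        """No already-placed site within [lo, hi] on chrom."""
        arr = self.placed[chrom]
        i = bisect_left(arr, lo)
        return not (i < len(arr) and arr[i] <= hi)

    def place_one(self, max_tries: int = 10_000) -> tuple[str, int]:
        for _ in range(max_tries):
            ci = self.rng.choice(len(self.chroms), p=self.weights)
            chrom = self.chroms[ci]
            pos = int(self.rng.integers(1, int(self.lengths[ci]) + 1))
            if self._free(chrom, pos - self.spacing, pos + self.spacing):
                insort(self.placed[chrom], pos)
                return chrom, pos
        raise ConfigError("cannot place sites: genome too small for the requested count and spacing")

    def place_cluster(self, size: int, span: int, max_tries: int = 10_000) -> tuple[str, list[int]]:
        for _ in range(max_tries):
            ci = self.rng.choice(len(self.chroms), p=self.weights)
            chrom = self.chroms[ci]
            L = int(self.lengths[ci])
            if L < span + 2:
                continue
            anchor = int(self.rng.integers(1, L - span + 1))
            if not self._free(chrom, anchor - self.spacing, anchor + span + self.spacing):
                continue
            offsets = self.rng.choice(span + 1, size=min(size, span + 1), replace=False)
            positions = sorted(int(anchor + o) for o in offsets)
            for p in positions:
                insort(self.placed[chrom], p)
            return chrom, positions
        raise ConfigError("cannot place a paralog cluster: genome too small")


# ---------------------------------------------------------------------------
# truth sampling
# ---------------------------------------------------------------------------


def sample_true_variants(config: SyntheticConfig, rng: np.random.Generator | None = None,
                         placer: _Placer | None = None) -> list[TruthRecord]:
    """Draw each strain's equilibrium variants (positions, SFS elements)."""
    rng = rng or np.random.default_rng(config.seed)
    placer = placer or _Placer(config.chromosomes, config.min_site_spacing, rng)
    model = build_markov_model(config.mating)
    _, proportions, _ = expected_sfs(model)
    records: list[TruthRecord] = []
    for strain in config.strains:
        expected = expected_segregating_sites(model, strain.mu, config.total_L)
        n = int(rng.poisson(expected))
        if n > config.total_L:
            raise ConfigError(f"strain {strain.name}: {n} variants exceed the genome size")
        element_counts = rng.multinomial(n, proportions.counts)
        for element, k in zip(ELEMENTS, element_counts):
            for _ in range(int(k)):
                chrom, pos = placer.place_one()
                records.append(TruthRecord(chrom, pos, strain.name, "true_variant", element))
    return records


def inject_artifacts(config: SyntheticConfig, truth: list[TruthRecord],
                     rng: np.random.Generator | None = None,
                     placer: _Placer | None = None) -> list[TruthRecord]:
    """Append labelled artifact sites to the truth set."""
    rng = rng or np.random.default_rng(config.seed + 1)
    if placer is None:
        placer = _Placer(config.chromosomes, config.min_site_spacing, rng)
        for t in truth:
            insort(placer.placed[t.chrom], t.pos)
    art = config.artifacts
    L = config.total_L
    strain_names = [s.name for s in config.strains]
    out = list(truth)

    n_clusters = rng.poisson(art.paralog_cluster * L)
    for k in range(n_clusters):
        size = int(rng.integers(art.cluster_size[0], art.cluster_size[1] + 1))
        chrom, positions = placer.place_cluster(size, art.cluster_span)
        strain = strain_names[rng.integers(len(strain_names))]
        for p in positions:
            out.append(TruthRecord(chrom, p, strain, "paralog_cluster", "RARA", cluster_id=k))

    for klass in ("bait_impurity", "low_qual", "low_depth", "multiallelic", "indel"):
        for _ in range(rng.poisson(getattr(art, klass) * L)):
            chrom, pos = placer.place_one()
            strain = strain_names[rng.integers(len(strain_names))]
            element = "RARA" if klass == "multiallelic" else "RARR"
            out.append(TruthRecord(chrom, pos, strain, klass, element))
    return out


# ---------------------------------------------------------------------------
# VCF rendering
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    truth: list[TruthRecord]
    vcf_path: Path
    truth_path: Path
    roles_path: Path
    callable_path: Path

    @property
    def roles(self) -> SampleRoleMap:
        return self.config.roles()

    def true_sfs(self, strain: str):
        from .sfs import SFSVector

        return SFSVector.from_elements(
            t.element for t in self.truth if t.strain == strain and t.klass == "true_variant"
        )


def _hom_ref_call(dp: int) -> tuple[str, str, int, None]:
    return "0/0", f"{dp},0", dp, None


def _het_call(rng: np.random.Generator, dp: int, min_balance: float) -> tuple[str, str, int, None]:
    # callable het evidence: balance conditioned above the review threshold
    while True:
        alt = rng.binomial(dp, 0.5)
        if dp > 0 and min_balance <= alt / dp and alt >= 1:
            break
    return "0/1", f"{dp - alt},{alt}", dp, None


def _render_site(config: SyntheticConfig, t: TruthRecord, roles: SampleRoleMap,
                 rng: np.random.Generator) -> str:
    """One VCF data line for a truth record."""
    samples = roles.all_samples()
    inbred = set(roles.inbred_samples())
    depth = config.depth
    qual_lo, qual_hi = config.qual_range
    focal_a, focal_b = (roles.focal_pair(t.strain) if t.strain else (None, None))

    ref = _BASES[rng.integers(4)]
    alt_pool = [b for b in _BASES if b != ref]
    alt = alt_pool[rng.integers(3)]
    alts = [alt]
    qual = float(rng.uniform(qual_lo, qual_hi))
    fmt = "GT:AD:DP"
    n_alt_alleles = 1

    if t.klass == "low_qual":
        qual = float(rng.uniform(20.0, 89.0))
    elif t.klass == "multiallelic":
        alt2 = [b for b in alt_pool if b != alt][rng.integers(2)]
        alts = [alt, alt2]
        n_alt_alleles = 2
    elif t.klass == "indel":
        alts = [ref + alt]

    low_depth_sample = None
    if t.klass == "low_depth":
        pool = sorted(inbred)
        low_depth_sample = pool[rng.integers(len(pool))]

    bait_carriers: set[str] = set()
    if t.klass == "bait_impurity":
        # two stray alt reads in one bait sample (sequencing error / paralog leak)
        bait_carriers = {roles.bait[rng.integers(len(roles.bait))]} if roles.bait else set()

    if t.klass == "paralog_cluster":
        fmt = "GT:AD:DP:PS"

    calls = []
    for s in samples:
        is_inbred = s in inbred
        dp = int(
            depth.draw(rng, 1, minimum=config.min_dp if is_inbred else 1,
                       maximum=depth.callable_cap if is_inbred else None)[0]
        )
        gt, ad, sdp, ps = _hom_ref_call(dp)

        if t.klass in ("true_variant", "low_qual", "low_depth", "bait_impurity", "indel"):
            copies = ELEMENT_COPIES[t.element or "RARR"]
            which = 0 if s == focal_a else 1 if s == focal_b else None
            if which is not None:
                c = copies[which]
                if c == 1:
                    gt, ad, sdp, ps = _het_call(rng, dp, 0.25)
                elif c == 2:
                    gt, ad, sdp, ps = "1/1", f"0,{dp}", dp, None
        elif t.klass == "multiallelic":
            if s == focal_a:
                alt_n = rng.binomial(dp, 0.5)
                alt_n = max(alt_n, int(np.ceil(0.25 * dp)))
                gt, ad = "0/1", f"{dp - alt_n},{alt_n},0"
            elif s == focal_b:
                alt_n = rng.binomial(dp, 0.5)
                alt_n = max(alt_n, int(np.ceil(0.25 * dp)))
                gt, ad = "0/2", f"{dp - alt_n},0,{alt_n}"
            else:
                ad = f"{dp},0,0"
            sdp = dp
        elif t.klass == "paralog_cluster":
            if s in (focal_a, focal_b):
                # misaligned duplicate: depth well above twice the genomic mean
                dp = int(round(depth.mean * rng.uniform(2.3, 2.8)))
                alt_n = rng.binomial(dp, 0.5)
                alt_n = min(max(alt_n, int(np.ceil(0.3 * dp))), dp - 1)
                gt, ad, sdp = "0/1", f"{dp - alt_n},{alt_n}", dp
        if t.klass == "low_depth" and s == low_depth_sample:
            dp = int(rng.integers(1, config.min_dp))
            if gt == "0/1":
                alt_n = max(1, rng.binomial(dp, 0.5))
                ad, sdp = f"{dp - alt_n},{alt_n}", dp
            else:
                ad, sdp = f"{dp},0", dp
        if s in bait_carriers:
            dp = max(dp, 5)
            ad, sdp = f"{dp - 2},2", dp

        if n_alt_alleles == 2 and ad.count(",") == 1:
            ad = ad + ",0"
        if t.klass == "paralog_cluster":
            ps_val = str(_cluster_ps(t)) if s in (focal_a, focal_b) else "."
            calls.append(f"{gt}:{ad}:{sdp}:{ps_val}")
        else:
            calls.append(f"{gt}:{ad}:{sdp}")

    line = (
        f"{t.chrom}\t{t.pos}\t.\t{ref}\t{','.join(alts)}\t{qual:.2f}\t.\t.\t{fmt}\t"
        + "\t".join(calls)
    )
    return line


_CLUSTER_PS_BASE = 1_000_000


def _cluster_ps(t: TruthRecord) -> int:
    return _CLUSTER_PS_BASE + (t.cluster_id or 0)


def _vcf_header(config: SyntheticConfig, samples: Sequence[str]) -> str:
    lines = ["##fileformat=VCFv4.2", "##source=sibline-synth"]
    for chrom, length in config.chromosomes.items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    return "\n".join(lines) + "\n"


def write_vcf_and_truth(
    config: SyntheticConfig,
    records: Sequence[TruthRecord],
    out_dir: str | Path,
    all_sites: bool = False,
    rng: np.random.Generator | None = None,
) -> SyntheticDataset:
    """Serialise truth records as a VCF plus truth/roles/callable sidecars.

    ``all_sites`` additionally emits a hom-ref record for every untouched
    position (feasible only for small genomes); callable-site counts are
    always written to the sidecar TSV.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputError(f"cannot create output directory {out}: {exc}") from None
    if all_sites and config.total_L > 200_000:
        raise ConfigError("all-sites mode is intended for L <= 2e5")

    roles = config.roles()
    samples = roles.all_samples()
    chrom_order = {c: i for i, c in enumerate(config.chromosomes)}
    records = sorted(records, key=lambda t: (chrom_order[t.chrom], t.pos))

    # callable sites: configured L minus emitted records failing criteria 1-4
    non_callable = {"bait_impurity", "low_qual", "low_depth"}
    per_chrom = {c: int(L) for c, L in config.chromosomes.items()}
    for t in records:
        if t.klass in non_callable:
            per_chrom[t.chrom] -= 1

    vcf_path = out / "synthetic.vcf"
    with open(vcf_path, "w") as fh:
        fh.write(_vcf_header(config, samples))
        if all_sites:
            by_pos = {(t.chrom, t.pos): t for t in records}
            for chrom, L in config.chromosomes.items():
                for pos in range(1, int(L) + 1):
                    t = by_pos.get((chrom, pos))
                    if t is not None:
                        fh.write(_render_site(config, t, roles, rng) + "\n")
                    else:
                        fh.write(_render_monomorphic(config, chrom, pos, roles, rng) + "\n")
        else:
            for t in records:
                fh.write(_render_site(config, t, roles, rng) + "\n")

    truth_path = out / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("chrom\tpos\tstrain\tclass\telement\tcluster_id\n")
        for t in records:
            fh.write(
                f"{t.chrom}\t{t.pos}\t{t.strain or 'NA'}\t{t.klass}\t{t.element or 'NA'}\t"
                f"{t.cluster_id if t.cluster_id is not None else 'NA'}\n"
            )

    roles_path = out / "roles.yaml"
    roles.to_yaml(roles_path)
    callable_path = out / "callable_sites.tsv"
    CallableSiteTally(per_chromosome=per_chrom).to_tsv(callable_path)

    return SyntheticDataset(
        config=config,
        truth=list(records),
        vcf_path=vcf_path,
        truth_path=truth_path,
        roles_path=roles_path,
        callable_path=callable_path,
    )


def _render_monomorphic(config: SyntheticConfig, chrom: str, pos: int,
                        roles: SampleRoleMap, rng: np.random.Generator) -> str:
    samples = roles.all_samples()
    inbred = set(roles.inbred_samples())
    ref = _BASES[rng.integers(4)]
    calls = []
    for s in samples:
        is_inbred = s in inbred
        dp = int(
            config.depth.draw(rng, 1, minimum=config.min_dp if is_inbred else 1,
                              maximum=config.depth.callable_cap if is_inbred else None)[0]
        )
        calls.append(f"0/0:{dp}:{dp}")
    return f"{chrom}\t{pos}\t.\t{ref}\t.\t.\t.\t.\tGT:AD:DP\t" + "\t".join(calls)


def generate(config: SyntheticConfig, out_dir: str | Path, all_sites: bool = False) -> SyntheticDataset:
    """End-to-end generation: truth draw, artifact injection, serialisation."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    placer = _Placer(config.chromosomes, config.min_site_spacing, rng)
    truth = sample_true_variants(config, rng, placer)
    truth = inject_artifacts(config, truth, rng, placer)
    return write_vcf_and_truth(config, truth, out_dir, all_sites=all_sites, rng=rng)


def read_truth_tsv(path: str | Path) -> list[TruthRecord]:
    out = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            chrom, pos, strain, klass, element, cluster = line.rstrip("\n").split("\t")
            out.append(
                TruthRecord(
                    chrom, int(pos),
                    None if strain == "NA" else strain,
                    klass,
                    None if element == "NA" else element,
                    None if cluster == "NA" else int(cluster),
                )
            )
    return out
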