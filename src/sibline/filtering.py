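"""Strain-specific variant detection in a joint multi-sample VCF.

Sites are classified against a focal inbred pair while enforcing near
purity in every other sample: the inbred individuals of all other strains
and a panel of unrelated wild-mouse "bait" genomes.  Putative variants
shared with the baits are almost certainly misaligned paralogous sequence,
not recent mutations.

Primary (automated) criteria, evaluated per site:

1.  site QUAL >= 90
2.  read depth of every inbred sample >= 10
3.  total alt-supporting reads across all bait samples <= 1
4.  total alt-supporting reads across all non-focal inbred samples <= 1
5.  non-focal genotypes are all homozygous reference and the focal pair
    carries 1-3 alternative allele copies
6.  the site is a single-nucleotide variant

Secondary (review-stage) criteria, evaluated on primary-passing sites:

7.  heterozygous allele balance >= 0.25 in every heterozygous focal sample
8.  focal-pair read depth <= 2 x the mean genomic focal-pair depth
9.  the site is not in a phase/proximity cluster with another candidate
10. no more than two alleles
11. read-mate placement on other chromosomes (requires BAM evidence; always
    recorded as not evaluated here -- an extension point, not a filter)

Sites passing 1-6 are "pre-check" sites; sites additionally passing 7-10
are "post-check" sites.  When the pre-check set is large, a random sample
(100 sites by convention) is review-checked and the post-check total is
extrapolated from the sample's pass fraction.  Mapping quality is
deliberately not used: it is not available uniformly for variant and
non-variant sites in joint-genotyped output.

Criterion 1 at non-variant records: joint genotypers emit hom-ref blocks
without a comparable QUAL, so a missing QUAL on a record with no ALT
allele passes criterion 1 (override via ``FilterThresholds.qual_missing_nonvariant_passes``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .errors import ConfigError, InputError
from .sfs import A_CARRIER_ELEMENTS, B_CARRIER_ELEMENTS, SFSVector, classify_pair

logger = logging.getLogger(__name__)

PASS, FAIL, NOT_EVALUATED = "pass", "fail", "not_evaluated"

PRIMARY_CRITERIA = ("c1", "c2", "c3", "c4", "c5", "c6")
SECONDARY_CRITERIA = ("c7", "c8", "c9", "c10")
ALL_CRITERIA = PRIMARY_CRITERIA + SECONDARY_CRITERIA + ("c11",)

_SYMBOLIC = {"<NON_REF>", "<*>", "*", "."}


@dataclass(frozen=True)
class FilterThresholds:
    min_qual: float = 90.0
    min_dp_inbred: int = 10
    max_bait_alt_reads: int = 1
    max_nonfocal_alt_reads: int = 1
    max_focal_alt_alleles: int = 3
    min_het_allele_balance: float = 0.25
    max_depth_factor: float = 2.0
    max_alleles: int = 2
    phase_cluster_window: int = 100  # bp
    depth_subsample_stride: int = 1  # every k-th record feeds the depth estimate
    qual_missing_nonvariant_passes: bool = True

    def __post_init__(self) -> None:
        for name in ("min_qual", "min_dp_inbred", "max_bait_alt_reads", "max_nonfocal_alt_reads",
                     "max_focal_alt_alleles", "min_het_allele_balance", "max_depth_factor",
                     "max_alleles", "phase_cluster_window"):
            if getattr(self, name) < 0:
                raise ConfigError(f"threshold {name} must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterThresholds":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from None


@dataclass
class SampleRoleMap:
    """Which VCF sample is which: per-strain focal pairs, other inbred
    samples, and wild bait samples."""

    strains: dict[str, tuple[str, str]]
    other_inbred: tuple[str, ...] = ()
    bait: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for strain, pair in self.strains.items():
            if len(pair) != 2:
                raise ConfigError(f"strain {strain!r} must have exactly two focal samples")
            self.strains[strain] = tuple(pair)
        self.other_inbred = tuple(self.other_inbred)
        self.bait = tuple(self.bait)
        names = list(self.all_samples())
        if len(set(names)) != len(names):
            raise ConfigError("duplicate sample names in role map")
        if not self.bait:
            warnings.warn("no bait (wild) samples configured; paralog bait-filtering is disabled", stacklevel=2)

    def focal_pair(self, strain: str) -> tuple[str, str]:
        try:
            return self.strains[strain]
        except KeyError:
            raise ConfigError(f"unknown strain {strain!r}") from None

    def inbred_samples(self) -> tuple[str, ...]:
        out: list[str] = []
        for pair in self.strains.values():
            out.extend(pair)
        out.extend(self.other_inbred)
        return tuple(out)

    def nonfocal_inbred(self, strain: str) -> tuple[str, ...]:
        focal = set(self.focal_pair(strain))
        return tuple(s for s in self.inbred_samples() if s not in focal)

    def all_samples(self) -> tuple[str, ...]:
        return self.inbred_samples() + self.bait

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SampleRoleMap":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict) or "strains" not in data:
            raise ConfigError(f"{path}: role map must define 'strains'")
        return cls(
            strains={k: tuple(v) for k, v in data["strains"].items()},
            other_inbred=tuple(data.get("other_inbred", []) or []),
            bait=tuple(data.get("bait", []) or []),
        )

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "strains": {k: list(v) for k, v in self.strains.items()},
            "other_inbred": list(self.other_inbred),
            "bait": list(self.bait),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class SiteCall:
    """One VCF record: alleles, QUAL, and per-sample GT/DP/AD (+ phase set)."""

    chrom: str
    pos: int  # 1-based, VCF native
    ref: str
    alts: tuple[str, ...]
    qual: float | None
    gts: dict[str, tuple[int, int] | None]  # allele indices; None = missing
    dp: dict[str, int | None]
    ad: dict[str, tuple[int, ...] | None]
    ps: dict[str, int | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InputError(f"{self.chrom}:{self.pos}: VCF positions are 1-based")

    @property
    def is_variant(self) -> bool:
        return any(a not in _SYMBOLIC for a in self.alts)

    def alt_copies(self, sample: str) -> int | None:
        """Number of alternative allele copies in a diploid genotype."""
        gt = self.gts.get(sample)
        if gt is None or len(gt) != 2 or any(a < 0 for a in gt):
            return None
        return sum(1 for a in gt if a > 0)

    def alt_read_count(self, sample: str) -> int | None:
        ad = self.ad.get(sample)
        if ad is None:
            return None
        return int(sum(ad[1:]))


@dataclass
class FilterDecision:
    chrom: str
    pos: int
    strain: str
    flags: dict[str, str] = field(default_factory=lambda: {c: NOT_EVALUATED for c in ALL_CRITERIA})
    element: str | None = None

    @property
    def overall_primary(self) -> bool:
        return all(self.flags[c] == PASS for c in PRIMARY_CRITERIA)

    @property
    def overall_secondary(self) -> bool:
        return all(self.flags[c] == PASS for c in SECONDARY_CRITERIA)

    @property
    def first_failing(self) -> str | None:
        """First criterion responsible for rejection (``not_evaluated`` on an
        evaluated stage fails closed); None for a clean pass."""
        for c in ALL_CRITERIA:
            if c != "c11" and self.flags[c] == FAIL:
                return c
        for c in PRIMARY_CRITERIA:
            if self.flags[c] == NOT_EVALUATED:
                return c
        if any(self.flags[c] != NOT_EVALUATED for c in SECONDARY_CRITERIA):
            for c in SECONDARY_CRITERIA:
                if self.flags[c] == NOT_EVALUATED:
                    return c
        return None

    @property
    def failed_criteria(self) -> tuple[str, ...]:
        return tuple(c for c in ALL_CRITERIA if c != "c11" and self.flags[c] == FAIL)


@dataclass
class CallableSiteTally:
    """Sites passing criteria 1-4 (variant or not): the callable genome L."""

    per_chromosome: dict[str, int]

    @property
    def total(self) -> int:
        return int(sum(self.per_chromosome.values()))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chromosome\tcallable_sites\n")
            for chrom, n in self.per_chromosome.items():
                fh.write(f"{chrom}\t{n}\n")
            fh.write(f"total\t{self.total}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CallableSiteTally":
        per: dict[str, int] = {}
        with open(path) as fh:
            fh.readline()
            for line in fh:
                if not line.strip():
                    continue
                chrom, n = line.split("\t")[:2]
                if chrom != "total":
                    per[chrom] = int(n)
        return cls(per_chromosome=per)


# ---------------------------------------------------------------------------
# genotype classification
# ---------------------------------------------------------------------------


def classify_focal_genotypes(gt_a: tuple[int, int] | None, gt_b: tuple[int, int] | None) -> str | None:
    """Map the focal pair's genotypes to an SFS element (None if monomorphic
    or not classifiable)."""
    for gt in (gt_a, gt_b):
        if gt is None or len(gt) != 2 or any(a < 0 for a in gt):
            return None
    a = sum(1 for x in gt_a if x > 0)
    b = sum(1 for x in gt_b if x > 0)
    return classify_pair(a, b)


# ---------------------------------------------------------------------------
# criteria
# ---------------------------------------------------------------------------


def _sum_alt_reads(site: SiteCall, samples: Iterable[str]) -> tuple[int | None, bool]:
    """(total alt reads, any AD missing) over the given samples."""
    total = 0
    missing = False
    for s in samples:
        n = site.alt_read_count(s)
        if n is None:
            missing = True
        else:
            total += n
    return total, missing


def apply_primary_criteria(
    site: SiteCall,
    roles: SampleRoleMap,
    focal_strain: str,
    thr: FilterThresholds = FilterThresholds(),
) -> FilterDecision:
    """Evaluate the automated criteria 1-6 and assign the SFS element.

    Alt-read purity (criteria 3 and 4) counts reads via the AD field summed
    over alt alleles -- genotype calls are ignored for purity.  A missing
    AD where alt-read counting is needed marks the criterion not evaluated
    and the site fails closed.
    """
    dec = FilterDecision(chrom=site.chrom, pos=site.pos, strain=focal_strain)
    focal_a, focal_b = roles.focal_pair(focal_strain)
    nonfocal = roles.nonfocal_inbred(focal_strain)

    # c1: site quality
    if site.qual is None:
        if not site.is_variant and thr.qual_missing_nonvariant_passes:
            dec.flags["c1"] = PASS
        else:
            dec.flags["c1"] = FAIL
    else:
        dec.flags["c1"] = PASS if site.qual >= thr.min_qual else FAIL

    # c2: depth of every inbred sample
    dps = [site.dp.get(s) for s in roles.inbred_samples()]
    dec.flags["c2"] = PASS if all(d is not None and d >= thr.min_dp_inbred for d in dps) else FAIL

    # c3/c4: read purity in baits and non-focal inbreds
    if not site.is_variant:
        dec.flags["c3"] = PASS
        dec.flags["c4"] = PASS
    else:
        for flag, samples, cap in (
            ("c3", roles.bait, thr.max_bait_alt_reads),
            ("c4", nonfocal, thr.max_nonfocal_alt_reads),
        ):
            total, missing = _sum_alt_reads(site, samples)
            if missing:
                dec.flags[flag] = NOT_EVALUATED
                logger.debug("%s:%d %s not evaluated: missing AD", site.chrom, site.pos, flag)
            else:
                dec.flags[flag] = PASS if total <= cap else FAIL

    # c5: focal pair polymorphic against an otherwise hom-ref background
    if not site.is_variant:
        dec.flags["c5"] = FAIL
    else:
        background_homref = all(
            site.alt_copies(s) == 0 for s in (*nonfocal, *roles.bait)
        )
        ca, cb = site.alt_copies(focal_a), site.alt_copies(focal_b)
        if ca is None or cb is None:
            dec.flags["c5"] = FAIL  # missing focal genotype: fail closed
        else:
            combined = ca + cb
            dec.flags["c5"] = (
                PASS if background_homref and 1 <= combined <= thr.max_focal_alt_alleles else FAIL
            )

    # c6: single-nucleotide variant
    dec.flags["c6"] = (
        PASS
        if site.is_variant
        and len(site.ref) == 1
        and all(len(a) == 1 and a not in _SYMBOLIC for a in site.alts)
        else FAIL
    )

    if dec.overall_primary:
        dec.element = classify_focal_genotypes(site.gts.get(focal_a), site.gts.get(focal_b))
    return dec


def apply_secondary_criteria(
    site: SiteCall,
    decision: FilterDecision,
    roles: SampleRoleMap,
    context: Sequence[SiteCall],
    mean_pair_depth: float,
    thr: FilterThresholds = FilterThresholds(),
) -> FilterDecision:
    """Evaluate the review-stage criteria 7-10 on a primary-passing site.

    ``context`` holds the other primary-passing candidate sites of the same
    focal strain (for the phase/proximity clustering rule, criterion 9).
    ``mean_pair_depth`` is the mean genomic read depth of the focal pair
    (sum of the two DP values).
    """
    if not decision.overall_primary:
        raise ValueError("secondary criteria apply to primary-passing sites only")
    focal = roles.focal_pair(decision.strain)

    # c7: heterozygous allele balance
    flag = PASS
    for s in focal:
        if site.alt_copies(s) == 1:
            ad = site.ad.get(s)
            if ad is None or sum(ad) == 0:
                flag = NOT_EVALUATED
                break
            balance = sum(ad[1:]) / sum(ad)
            if balance < thr.min_het_allele_balance:
                flag = FAIL
                break
    decision.flags["c7"] = flag

    # c8: focal-pair depth cap
    pair_dp = [site.dp.get(s) for s in focal]
    if any(d is None for d in pair_dp) or mean_pair_depth <= 0:
        decision.flags["c8"] = NOT_EVALUATED
    else:
        decision.flags["c8"] = (
            PASS if sum(pair_dp) <= thr.max_depth_factor * mean_pair_depth else FAIL
        )

    # c9: phase/proximity cluster with another candidate
    clustered = False
    own_ps = {site.ps.get(s) for s in focal if site.ps.get(s) is not None}
    for other in context:
        if other.chrom != site.chrom or other.pos == site.pos:
            continue
        if abs(other.pos - site.pos) <= thr.phase_cluster_window:
            clustered = True
            break
        if own_ps and own_ps & {other.ps.get(s) for s in focal if other.ps.get(s) is not None}:
            clustered = True
            break
    decision.flags["c9"] = FAIL if clustered else PASS

    # c10: at most two alleles
    decision.flags["c10"] = PASS if 1 + len(site.alts) <= thr.max_alleles else FAIL

    # c11 needs BAM mate placement; recorded but never evaluated at VCF level
    decision.flags["c11"] = NOT_EVALUATED
    return decision


# ---------------------------------------------------------------------------
# VCF streaming
# ---------------------------------------------------------------------------


def _to_int(x) -> int | None:
    try:
        v = int(x)
    except (TypeError, ValueError):
        return None
    return v if v >= 0 else None


def site_from_cyvcf(variant, samples: Sequence[str]) -> SiteCall:
    """Convert a cyvcf2 Variant into a :class:`SiteCall`."""
    gts: dict[str, tuple[int, int] | None] = {}
    for s, g in zip(samples, variant.genotypes):
        alleles = tuple(int(a) for a in g[:-1])
        gts[s] = alleles if len(alleles) == 2 else None

    def fmt(name):
        try:
            return variant.format(name)
        except KeyError:
            return None

    dp_arr = fmt("DP")
    ad_arr = fmt("AD")
    ps_arr = fmt("PS")
    dp = {}
    ad = {}
    ps = {}
    for i, s in enumerate(samples):
        dp[s] = _to_int(dp_arr[i][0]) if dp_arr is not None else None
        if ad_arr is not None:
            row = [int(x) for x in np.atleast_1d(ad_arr[i])]
            # cyvcf2 encodes missing AD as negative sentinels
            ad[s] = None if not row or row[0] < 0 else tuple(max(x, 0) for x in row)
        else:
            ad[s] = None
        ps[s] = _to_int(ps_arr[i][0]) if ps_arr is not None else None
    alts = tuple(a for a in (variant.ALT or []))
    return SiteCall(
        chrom=variant.CHROM,
        pos=int(variant.POS),
        ref=variant.REF,
        alts=alts,
        qual=None if variant.QUAL is None else float(variant.QUAL),
        gts=gts,
        dp=dp,
        ad=ad,
        ps=ps,
    )


def read_sites(vcf_path: str | Path, variant_only: bool = True):
    """Yield :class:`SiteCall` records from a VCF (lazily)."""
    from cyvcf2 import VCF

    path = str(vcf_path)
    if not Path(path).exists():
        raise InputError(f"VCF not found: {path}")
    vcf = VCF(path)
    samples = list(vcf.samples)
    for variant in vcf:
        site = site_from_cyvcf(variant, samples)
        if variant_only and not site.is_variant:
            continue
        yield site


def estimate_mean_pair_depth(
    sites: Iterable[SiteCall],
    focal: tuple[str, str],
    stride: int = 100,
) -> float:
    """Mean focal-pair total DP over every ``stride``-th record."""
    vals = []
    for i, site in enumerate(sites):
        if i % max(stride, 1):
            continue
        dps = [site.dp.get(s) for s in focal]
        if all(d is not None for d in dps):
            vals.append(sum(dps))
    if not vals:
        raise InputError("cannot estimate mean depth: no records with focal DP")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# the per-strain filtering run
# ---------------------------------------------------------------------------


@dataclass
class StrainFilterResult:
    strain: str
    decisions: list[FilterDecision]
    pre_check: list[FilterDecision]  # primary-passing
    post_check: list[FilterDecision]  # secondary-evaluated and passing
    v: SFSVector  # observed post-check SFS (scaled if extrapolated)
    v_pre: SFSVector  # pre-check SFS
    per_individual: tuple[float, float]
    mean_pair_depth: float
    pass_fraction: float | None  # secondary pass fraction (sampled or full)
    extrapolated: bool
    n_secondary_checked: int

    @property
    def n_pre_check(self) -> int:
        return len(self.pre_check)

    @property
    def post_check_total(self) -> float:
        """Exact count, or the sampled-check extrapolation."""
        if self.extrapolated:
            return float(round(self.pass_fraction * self.n_pre_check))
        return float(len(self.post_check))


def sample_and_extrapolate(n_pre_check: int, secondary_pass_fraction: float, sample_size: int = 100) -> int:
    """Post-check total from a sampled review: round(fraction x pre-check count).

    When the pre-check count does not exceed the sample size every site is
    reviewed, so the "extrapolation" is exact by construction.
    """
    if sample_size == 0:
        raise ConfigError("sample_size must be positive")
    if not 0.0 <= secondary_pass_fraction <= 1.0:
        raise ValueError("pass fraction must be in [0, 1]")
    return int(round(secondary_pass_fraction * n_pre_check))


def build_observed_sfs(post_check: Sequence[FilterDecision]) -> tuple[SFSVector, tuple[float, float]]:
    """Observed SFS v and per-individual carrier counts from post-check sites.

    Individual A's tally counts sites where A carries at least one alt copy
    (elements RARR, RARA, AARR, AARA, RAAA); B's analogously.
    """
    v = SFSVector.from_elements(d.element for d in post_check if d.element)
    n_a = sum(1 for d in post_check if d.element in A_CARRIER_ELEMENTS)
    n_b = sum(1 for d in post_check if d.element in B_CARRIER_ELEMENTS)
    return v, (float(n_a), float(n_b))


def filter_strain(
    sites: Sequence[SiteCall] | str | Path,
    roles: SampleRoleMap,
    strain: str,
    thr: FilterThresholds = FilterThresholds(),
    mean_pair_depth: float | None = None,
    secondary_sample_size: int | None = None,
    rng: np.random.Generator | None = None,
) -> StrainFilterResult:
    """Run the full per-strain classification.

    ``sites`` may be a VCF path or an in-memory sequence of
    :class:`SiteCall`.  If ``secondary_sample_size`` is given and the
    pre-check set is larger, only a random sample of that size is
    review-checked and the post-check totals (and the observed SFS) are
    extrapolated from the sample pass fraction; otherwise every pre-check
    site is reviewed.
    """
    if isinstance(sites, (str, Path)):
        sites = list(read_sites(sites, variant_only=False))
    variant_sites = [s for s in sites if s.is_variant]
    focal = roles.focal_pair(strain)
    if mean_pair_depth is None:
        mean_pair_depth = estimate_mean_pair_depth(sites, focal, thr.depth_subsample_stride)

    decisions = [apply_primary_criteria(s, roles, strain, thr) for s in variant_sites]
    pre_sites = [s for s, d in zip(variant_sites, decisions) if d.overall_primary]
    pre_decs = [d for d in decisions if d.overall_primary]
    for d in decisions:
        if not d.overall_primary:
            logger.debug("%s:%d fails primary at %s", d.chrom, d.pos, d.first_failing)

    extrapolated = secondary_sample_size is not None and len(pre_sites) > secondary_sample_size
    if extrapolated:
        rng = rng or np.random.default_rng()
        idx = rng.choice(len(pre_sites), size=secondary_sample_size, replace=False)
        idx = np.sort(idx)
    else:
        idx = np.arange(len(pre_sites))

    checked = []
    for i in idx:
        d = apply_secondary_criteria(pre_sites[i], pre_decs[i], roles, pre_sites, mean_pair_depth, thr)
        checked.append(d)
    post = [d for d in checked if d.overall_secondary]
    pass_fraction = len(post) / len(checked) if checked else None

    v_pre, _ = build_observed_sfs(pre_decs)
    if extrapolated:
        v_post_exact, (na, nb) = build_observed_sfs(post)
        # scale the pre-check spectrum by the sampled pass fraction
        v = SFSVector(v_pre.counts * (pass_fraction if pass_fraction is not None else 0.0))
        per_ind_pre = (
            sum(v_pre[e] for e in A_CARRIER_ELEMENTS),
            sum(v_pre[e] for e in B_CARRIER_ELEMENTS),
        )
        per_individual = tuple(x * pass_fraction for x in per_ind_pre)
    else:
        v, per_individual = build_observed_sfs(post)

    return StrainFilterResult(
        strain=strain,
        decisions=decisions,
        pre_check=pre_decs,
        post_check=post,
        v=v,
        v_pre=v_pre,
        per_individual=per_individual,
        mean_pair_depth=mean_pair_depth,
        pass_fraction=pass_fraction,
        extrapolated=extrapolated,
        n_secondary_checked=len(checked),
    )


def count_callable_sites(
    vcf_or_sites: Sequence[SiteCall] | str | Path,
    roles: SampleRoleMap,
    thr: FilterThresholds = FilterThresholds(),
) -> CallableSiteTally:
    """Count sites (variant or not) passing criteria 1-4 per chromosome.

    Requires an all-sites (joint-genotyped with non-variant records) input;
    a VCF containing only variant records raises an error because L would
    otherwise be meaningless.
    """
    if isinstance(vcf_or_sites, (str, Path)):
        sites = read_sites(vcf_or_sites, variant_only=False)
    else:
        sites = iter(vcf_or_sites)
    per: dict[str, int] = {}
    saw_nonvariant = False
    saw_any = False
    for site in sites:
        saw_any = True
        if not site.is_variant:
            saw_nonvariant = True
        dec = apply_primary_criteria(site, roles, next(iter(roles.strains)), thr)
        if all(dec.flags[c] == PASS for c in ("c1", "c2", "c3", "c4")):
            per[site.chrom] = per.get(site.chrom, 0) + 1
    if saw_any and not saw_nonvariant:
        raise InputError(
            "callable-site counting needs an all-sites VCF (non-variant records included); "
            "this input contains variant records only"
        )
    return CallableSiteTally(per_chromosome=per)


def write_decisions_tsv(decisions: Sequence[FilterDecision], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tstrain\telement\t" + "\t".join(ALL_CRITERIA) + "\tprimary\tsecondary\n")
        for d in decisions:
            fh.write(
                f"{d.chrom}\t{d.pos}\t{d.strain}\t{d.element or 'NA'}\t"
                + "\t".join(d.flags[c] for c in ALL_CRITERIA)
                + f"\t{'pass' if d.overall_primary else 'fail'}"
                + f"\t{'pass' if d.overall_primary and d.overall_secondary else 'fail'}\n"
            )
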