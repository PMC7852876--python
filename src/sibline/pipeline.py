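"""End-to-end orchestration: data -> filter -> observed SFS -> rate estimate.

A single run takes a joint VCF (real or synthetic), a sample-role map and a
callable-site count, classifies strain-specific variants per strain,
builds the observed SFS v, pairs it with the expected SFS u (exact Markov
oracle by default, or a simulation ensemble to mirror the original
experiment literally), fits the mutation rate, and writes a report bundle
of TSV tables plus a JSON manifest sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .equilibrium import (
    REFERENCE_RATE,
    build_markov_model,
    expected_segregating_sites,
    expected_sfs,
    expected_sfs_counts_at,
    full_sib_effective_size,
)
from .errors import ConfigError, EstimationError, InputError
from .estimate import (
    BootstrapSpec,
    RateEstimate,
    effective_size_from_theta,
    estimate_rate,
    expected_variant_count,
)
from .filtering import (
    CallableSiteTally,
    FilterThresholds,
    SampleRoleMap,
    StrainFilterResult,
    count_callable_sites,
    filter_strain,
    read_sites,
    write_decisions_tsv,
)
from .sfs import ELEMENTS, SFSVector
from .simulate import SimParams, run_ensemble
from . import synth as synth_mod

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative run configuration (YAML-loadable).

    Exactly one data source: ``synth`` (generate a synthetic cohort) or
    ``inputs`` (paths to vcf/roles/callable sidecar).
    """

    seed: int = 0
    synth: synth_mod.SyntheticConfig | None = None
    vcf: str | None = None
    roles: str | None = None
    callable_sites: str | None = None  # sidecar TSV; or "vcf" to count from an all-sites VCF
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    expected_source: str = "oracle"  # "oracle" | "ensemble"
    mating: str = "wf_selfing"
    reference_rate: float = REFERENCE_RATE
    ensemble_replicates: int = 200
    excluded_elements: tuple[str, ...] = ("RARA",)
    bootstrap_replicates: int = 10_000
    secondary_sample_size: int | None = 100

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        kwargs = dict(data)
        if "synth" in kwargs and kwargs["synth"] is not None:
            s = dict(kwargs["synth"])
            if "strains" in s:
                s["strains"] = tuple(
                    synth_mod.StrainSpec(
                        x["name"], float(x["mu"]),
                        x.get("sample_a", f"{x['name']}_A"), x.get("sample_b", f"{x['name']}_B"),
                    )
                    for x in s["strains"]
                )
            if "artifacts" in s:
                s["artifacts"] = synth_mod.ArtifactRates(**s["artifacts"])
            if "depth" in s:
                s["depth"] = synth_mod.DepthModel(**s["depth"])
            kwargs["synth"] = synth_mod.SyntheticConfig(**s)
        if "thresholds" in kwargs:
            kwargs["thresholds"] = FilterThresholds(**(kwargs["thresholds"] or {}))
        if "excluded_elements" in kwargs:
            kwargs["excluded_elements"] = tuple(kwargs["excluded_elements"])
        try:
            cfg = cls(**kwargs)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from None
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.expected_source not in ("oracle", "ensemble"):
            raise ConfigError(f"expected_source must be 'oracle' or 'ensemble', not {self.expected_source!r}")
        if self.synth is None and (self.vcf is None or self.roles is None):
            raise ConfigError("configure either 'synth' or input paths 'vcf' and 'roles'")
        unknown = set(self.excluded_elements) - set(ELEMENTS)
        if unknown:
            raise ConfigError(f"unknown excluded elements: {sorted(unknown)}")


@dataclass
class StrainReport:
    strain: str
    L: int
    n_pre_check: int
    pass_fraction: float | None
    post_check_total: float
    extrapolated: bool
    v: SFSVector
    u: SFSVector
    per_individual: tuple[float, float]
    estimate: RateEstimate | None
    expected_count_diversity: float | None  # 4 mu Ne L
    expected_count_chain: float | None  # 4 mu L * mean lifetime
    ne_from_theta: float | None


@dataclass
class PipelineReport:
    config: PipelineConfig
    strains: list[StrainReport]
    callable: CallableSiteTally
    manifest: dict


def _expected_u(config: PipelineConfig, L: int) -> SFSVector:
    model = build_markov_model(config.mating)
    if config.expected_source == "oracle":
        return expected_sfs_counts_at(model, config.reference_rate, L)
    params = SimParams(
        L_per_chromosome=(L,),
        mu=config.reference_rate,
        replicates=config.ensemble_replicates,
        mating=config.mating,
        seed=config.seed + 101,
    )
    return run_ensemble(params).mean_counts


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> PipelineReport:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.validate()

    if config.synth is not None:
        ds = synth_mod.generate(config.synth, out / "synthetic")
        vcf_path, roles_path, callable_path = ds.vcf_path, ds.roles_path, ds.callable_path
        roles = ds.roles
        tally = CallableSiteTally.from_tsv(callable_path)
    else:
        vcf_path, roles_path = Path(config.vcf), Path(config.roles)
        if not vcf_path.exists():
            raise InputError(f"VCF not found: {vcf_path}")
        roles = SampleRoleMap.from_yaml(roles_path)
        if config.callable_sites in (None, "vcf"):
            tally = count_callable_sites(str(vcf_path), roles, config.thresholds)
        else:
            tally = CallableSiteTally.from_tsv(config.callable_sites)

    sites = list(read_sites(vcf_path, variant_only=False))
    if not any(s.is_variant for s in sites):
        raise InputError(f"{vcf_path}: no variant records")

    L = tally.total
    u = _expected_u(config, L)
    model = build_markov_model(config.mating)
    ne = full_sib_effective_size().Ne_full_sib
    excluded = set(config.excluded_elements)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(7,)))

    strain_reports: list[StrainReport] = []
    all_decisions = []
    for strain in roles.strains:
        res: StrainFilterResult = filter_strain(
            sites, roles, strain,
            thr=config.thresholds,
            secondary_sample_size=config.secondary_sample_size,
            rng=rng,
        )
        all_decisions.extend(res.decisions)
        est = None
        exp_div = exp_chain = ne_theta = None
        if res.v.total >= 1:
            est = estimate_rate(
                u, res.v, excluded,
                BootstrapSpec(replicates=config.bootstrap_replicates, seed=config.seed + 13),
            )
            exp_div = expected_variant_count(est.mu_hat_absolute, ne, L)
            exp_chain = expected_segregating_sites(model, est.mu_hat_absolute, L)
            ne_theta = effective_size_from_theta(res.post_check_total, est.mu_hat_absolute, L)
        else:
            logger.warning("strain %s: no observed variants; rate not estimable", strain)
        strain_reports.append(
            StrainReport(
                strain=strain,
                L=L,
                n_pre_check=res.n_pre_check,
                pass_fraction=res.pass_fraction,
                post_check_total=res.post_check_total,
                extrapolated=res.extrapolated,
                v=res.v,
                u=u,
                per_individual=res.per_individual,
                estimate=est,
                expected_count_diversity=exp_div,
                expected_count_chain=exp_chain,
                ne_from_theta=ne_theta,
            )
        )

    manifest = {
        "tool": "sibline",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "python": platform.python_version(),
        "seed": config.seed,
        "mating": config.mating,
        "expected_source": config.expected_source,
        "reference_rate": config.reference_rate,
        "excluded_elements": sorted(excluded),
        "bootstrap_replicates": config.bootstrap_replicates,
        "secondary_sample_size": config.secondary_sample_size,
        "thresholds": {k: getattr(config.thresholds, k) for k in vars(config.thresholds)},
        "inputs": {
            "vcf": str(vcf_path),
            "vcf_sha256": _sha256(vcf_path),
            "roles": str(roles_path),
        },
        "callable_sites_total": L,
    }

    report = PipelineReport(config=config, strains=strain_reports, callable=tally, manifest=manifest)
    write_report(report, all_decisions, out)
    return report


def write_report(report: PipelineReport, decisions, out_dir: Path) -> None:
    out = Path(out_dir)
    with open(out / "report.tsv", "w") as fh:
        fh.write(
            "strain\tL\tpre_check\tpass_fraction\tpost_check\textrapolated\t"
            "mu_hat_ref_units\tmu_hat_absolute\tci_low\tci_high\td_min\t"
            "expected_4muNeL\texpected_chain\tne_from_theta\tn_A\tn_B\n"
        )
        for s in report.strains:
            e = s.estimate
            def f(x, fmt="{:.6g}"):
                return "NA" if x is None else fmt.format(x)
            fh.write(
                f"{s.strain}\t{s.L}\t{s.n_pre_check}\t{f(s.pass_fraction)}\t"
                f"{s.post_check_total:.6g}\t{int(s.extrapolated)}\t"
                f"{f(e.mu_hat if e else None)}\t{f(e.mu_hat_absolute if e else None, '{:.6g}')}\t"
                f"{f(e.ci_low if e else None, '{:.6g}')}\t{f(e.ci_high if e else None, '{:.6g}')}\t"
                f"{f(e.d_min if e else None)}\t{f(s.expected_count_diversity)}\t"
                f"{f(s.expected_count_chain)}\t{f(s.ne_from_theta)}\t"
                f"{s.per_individual[0]:.6g}\t{s.per_individual[1]:.6g}\n"
            )
    with open(out / "sfs_observed.tsv", "w") as fh:
        fh.write("strain\t" + "\t".join(ELEMENTS) + "\n")
        for s in report.strains:
            fh.write(s.strain + "\t" + "\t".join(f"{s.v[e]:.6g}" for e in ELEMENTS) + "\n")
    with open(out / "sfs_expected.tsv", "w") as fh:
        fh.write("strain\t" + "\t".join(ELEMENTS) + "\n")
        for s in report.strains:
            fh.write(s.strain + "\t" + "\t".join(f"{s.u[e]:.6g}" for e in ELEMENTS) + "\n")
    report.callable.to_tsv(out / "callable_sites.tsv")
    write_decisions_tsv(decisions, out / "decisions.tsv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(report.manifest, fh, indent=2)
        fh.write("\n")
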