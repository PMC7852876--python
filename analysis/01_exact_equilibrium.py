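#!/usr/bin/env python
"""Exact equilibrium SFS of a two-sib inbred line, both offspring models.

Solves the absorbing genotype-pair chain (fundamental matrix) for the
expected sojourn time per SFS element, the equilibrium proportions, the
mean segregating lifetime of a mutation, and the full-sib effective size.
Writes results/01_oracle_sfs.tsv.
"""

from pathlib import Path

from sibline.equilibrium import (
    build_markov_model,
    expected_segregating_sites,
    expected_sfs,
    full_sib_effective_size,
)
from sibline.sfs import ELEMENTS

L_REF = 2_725_521_370
MU_REF = 1e-8
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = []
    for mating in ("wf_selfing", "sib_mating"):
        model = build_markov_model(mating)
        sojourn, props, lifetime = expected_sfs(model)
        total = expected_segregating_sites(model, MU_REF, L_REF)
        print(f"\n{mating}: mean mutation lifetime {lifetime:.4f} generations; "
              f"expected segregating sites at mu={MU_REF:g}, L={L_REF:,}: {total:.1f}")
        for e in ELEMENTS:
            print(f"  {e}: sojourn {sojourn[e]:.4f}  proportion {props[e]:.4f}")
            rows.append((mating, e, sojourn[e], props[e]))
        single = props["RARR"] + props["RRRA"]
        print(f"  single-alt share {single:.3f}; RARA/(AARA+RAAA) = "
              f"{props['RARA'] / (props['AARA'] + props['RAAA']):.3f}; "
              f"RARA/(AARR+RRAA) = {props['RARA'] / (props['AARR'] + props['RRAA']):.3f}")

    ne = full_sib_effective_size()
    print(f"\nfull-sib heterozygosity retention lambda = {ne.lambda_fs:.6f} "
          f"-> Ne = {ne.Ne_full_sib:.4f} (rounds to 2.6)")

    with open(OUT / "01_oracle_sfs.tsv", "w") as fh:
        fh.write("mating\telement\tsojourn_generations\tproportion\n")
        for mating, e, s, p in rows:
            fh.write(f"{mating}\t{e}\t{s:.10g}\t{p:.10g}\n")
    print(f"\nwrote {OUT / '01_oracle_sfs.tsv'}")


if __name__ == "__main__":
    main()
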