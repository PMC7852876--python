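#!/usr/bin/env python
"""Generate the synthetic four-strain cohort used by the downstream steps.

Four inbred strains (two focal individuals each) and twelve wild bait
samples over a 1 Mb callable genome, with per-strain mutation rates scaled
up (1e-5) so equilibrium variant counts land in the low hundreds, plus
every artifact class (paralog clusters, bait impurities, low-QUAL,
low-depth, multi-allelic, indel sites).  The VCF is bulky and goes under
scratch/ (regenerated deterministically); a per-class summary goes to
results/03_cohort_summary.tsv.
"""

from collections import Counter
from pathlib import Path

from sibline.synth import SyntheticConfig, generate

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "cohort"
OUT = ROOT / "results"
SEED = 20260902


def build_cohort() -> "object":
    """Deterministic cohort shared by steps 03-05."""
    return generate(SyntheticConfig(seed=SEED), SCRATCH)


def main() -> None:
    OUT.mkdir(exist_ok=True)
    ds = build_cohort()
    counts = Counter((t.strain, t.klass) for t in ds.truth)
    strains = [s.name for s in ds.config.strains]
    classes = sorted({t.klass for t in ds.truth})
    print(f"wrote {ds.vcf_path} ({len(ds.truth)} sites)")
    print("strain  " + "  ".join(classes))
    with open(OUT / "03_cohort_summary.tsv", "w") as fh:
        fh.write("strain\t" + "\t".join(classes) + "\n")
        for s in strains:
            row = [counts.get((s, k), 0) for k in classes]
            print(f"  {s}: " + "  ".join(str(x) for x in row))
            fh.write(s + "\t" + "\t".join(str(x) for x in row) + "\n")
    print(f"callable sites: {ds.config.total_L} configured; sidecar at {ds.callable_path}")
    print(f"wrote {OUT / '03_cohort_summary.tsv'}")


if __name__ == "__main__":
    main()
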