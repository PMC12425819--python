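#!/usr/bin/env python
"""Simulate the paired exposed/control cohort and write the study fixtures.

Generates a 21-sample tamoxifen-associated (exposed) cohort and a 554-sample
de novo (control) cohort under the default study conditions: PIK3CA mutated
in 14% vs 48% of samples, PIK3R1 in 0% vs 31%, a TCGA-like molecular-subtype
mix, and subtype-scaled mutational burden over a 37-Mb exome territory.
Writes MAF/SEG/annotation TSVs plus the synthetic signature catalog under
results/cohorts/.
"""

from pathlib import Path

from tamuc.io import write_annotations, write_maf, write_seg
from tamuc.simulate import SimConfig, simulate_cohort_pair, synthetic_catalog

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "cohorts"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = SimConfig(seed=SEED)
    catalog = synthetic_catalog(seed=SEED)
    exposed, control, truth = simulate_cohort_pair(config, catalog, with_truth=True)

    write_maf(exposed.mutations + control.mutations, OUT / "mutations.maf.tsv")
    write_seg(exposed.segments + control.segments, OUT / "segments.seg.tsv")
    write_annotations(exposed.annotations + control.annotations,
                      OUT / "annotations.tsv")
    catalog.to_tsv(OUT / "signature_catalog.tsv")
    with open(OUT / "planted_subtypes.tsv", "w") as fh:
        fh.write("sample_id\tsubtype\n")
        for sid, st in truth.items():
            fh.write(f"{sid}\t{st}\n")

    k_pik3ca = len({m.sample_id for m in exposed.mutations if m.gene == "PIK3CA"})
    k_pik3ca_c = len({m.sample_id for m in control.mutations if m.gene == "PIK3CA"})
    print(f"wrote cohorts to {OUT}")
    print(f"  exposed: {exposed.n_samples} samples, {len(exposed.mutations)} mutations")
    print(f"  control: {control.n_samples} samples, {len(control.mutations)} mutations")
    print(f"  PIK3CA mutated: {k_pik3ca}/{exposed.n_samples} exposed vs "
          f"{k_pik3ca_c}/{control.n_samples} control")


if __name__ == "__main__":
    main()
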