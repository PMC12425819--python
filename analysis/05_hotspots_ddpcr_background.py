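#!/usr/bin/env python
"""Hotspot frequencies, ddPCR calling and the background-risk expectation.

1. PIK3CA hotspot (E542K/E545K/H1047R) frequency comparison between the
   simulated cohorts, via the hotspot-restricted binarization.
2. Simulated ddPCR plates: planted positives at 5% allele fraction among
   FFPE-noise negatives, called at the >2% AF cutoff.
3. The expected number of tamoxifen-unrelated (background) cases among the
   exposed patients under a fivefold absolute-risk increase.

Writes results/hotspots/*.tsv.
"""

from pathlib import Path

import pandas as pd

from tamuc.io import Cohort, GeneList, binarize, read_annotations, read_maf
from tamuc.simulate import PIK3CA_HOTSPOTS, simulate_ddpcr_wells
from tamuc.stats import FrequencyEstimate, fisher_2x2
from tamuc.summaries import (
    DdpcrParams,
    RiskParams,
    call_ddpcr,
    ddpcr_af,
    expected_background_cases,
)

ROOT = Path(__file__).resolve().parent.parent
COHORTS = ROOT / "results" / "cohorts"
OUT = ROOT / "results" / "hotspots"
SEED = 1


def _load(label: str) -> Cohort:
    anns = [a for a in read_annotations(COHORTS / "annotations.tsv")
            if a.cohort == label]
    sids = {a.sample_id for a in anns}
    muts = [m for m in read_maf(COHORTS / "mutations.maf.tsv")
            if m.sample_id in sids]
    return Cohort(annotations=anns, mutations=muts)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    exposed, control = _load("exposed"), _load("control")
    panel = GeneList("hotspots", ("PIK3CA",),
                     hotspots={"PIK3CA": frozenset(PIK3CA_HOTSPOTS)})

    rows = []
    for mode, hotspot_only in (("all_mutations", False), ("hotspot_only", True)):
        k1 = int(binarize(exposed, panel, hotspot_only).loc["PIK3CA"].sum())
        k2 = int(binarize(control, panel, hotspot_only).loc["PIK3CA"].sum())
        n1, n2 = exposed.n_samples, control.n_samples
        res = fisher_2x2([[k1, n1 - k1], [k2, n2 - k2]])
        e1, e2 = FrequencyEstimate(k1, n1), FrequencyEstimate(k2, n2)
        rows.append({"mode": mode, "k1": k1, "n1": n1, "freq1": e1.freq,
                     "sd1": e1.sd, "k2": k2, "n2": n2, "freq2": e2.freq,
                     "sd2": e2.sd, "p": res.p_value})
        print(f"PIK3CA {mode}: {k1}/{n1} vs {k2}/{n2}, P = {res.p_value:.2g}")
    pd.DataFrame(rows).to_csv(OUT / "pik3ca_hotspot_comparison.tsv", sep="\t",
                              index=False)

    wells = simulate_ddpcr_wells(3, 36, droplets=10_000, positive_af=0.05,
                                 seed=SEED)
    params = DdpcrParams()
    wells["af_percent"] = [ddpcr_af(m, w) for m, w in
                           zip(wells["mutant_droplets"],
                               wells["wildtype_droplets"])]
    wells["call"] = [call_ddpcr(m, w, params) for m, w in
                     zip(wells["mutant_droplets"], wells["wildtype_droplets"])]
    wells.to_csv(OUT / "ddpcr_calls.tsv", sep="\t", index=False)
    n_pos = int((wells["call"] == "positive").sum())
    print(f"ddPCR: {n_pos}/{len(wells)} wells positive at "
          f">{params.af_cutoff_percent:g}% AF")

    value, presented = expected_background_cases(exposed.n_samples, RiskParams())
    print(f"expected background cases among {exposed.n_samples} exposed "
          f"patients: {value:.1f} (~{presented})")
    with open(OUT / "background_risk.tsv", "w") as fh:
        fh.write("n_exposed\tbaseline_risk\ttreated_risk\texpected\tpresented\n")
        fh.write(f"{exposed.n_samples}\t0.005\t0.025\t{value}\t{presented}\n")


if __name__ == "__main__":
    main()
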