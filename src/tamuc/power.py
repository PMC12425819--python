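"""Fixed-margin power analysis for two-cohort Fisher frequency comparisons.

With a small exposed cohort, many driver genes cannot reach significance no
matter how the mutated samples are distributed between cohorts.  The power
gate makes this explicit: holding the observed margins fixed (cohort sizes
n1, n2 and the combined mutated count m) it enumerates every admissible 2x2
table, computes the Fisher P value of each, and takes the minimum — the best
P value any effect size could achieve.  A gene is *powered* when that
minimal P value, Bonferroni-corrected for the number of genes screened,
stays below alpha.  Only powered genes proceed to the actual frequency test,
so unpowered genes can never produce a spuriously "nonsignificant" result
that is in truth an uninformative one.

The complementary scan asks: with zero mutated samples observed in the
exposed cohort, how many mutated control samples are needed before a
one-sided deficit becomes detectable at alpha?
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Cohort, GeneList, binarize
from .stats import (
    FrequencyEstimate,
    bh_adjust,
    fisher_2x2,
    fisher_pvalues_all_tables,
)


@dataclass(frozen=True)
class MarginSpec:
    """Fixed margins of a 2x2 cohort-comparison table."""

    n1: int  # exposed cohort size
    n2: int  # control cohort size
    m: int   # total mutated samples across both cohorts

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("cohort sizes must be positive")
        if not (0 <= self.m <= self.n1 + self.n2):
            raise ValueError(f"m={self.m} outside [0, {self.n1 + self.n2}]")


@dataclass(frozen=True)
class PowerParams:
    """Alpha level, Bonferroni divisor and sidedness for the power gate.

    The divisor is the size of the upstream driver screen (49 genes for the
    two-sided comparison, 30 for the one-sided reduced-frequency screen in
    the motivating study); it is an input, not inferred.
    """

    alpha: float = 0.05
    n_tests: int = 1
    sidedness: str = "two_sided"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_tests < 1:
            raise ValueError("n_tests must be >= 1")


@dataclass(frozen=True)
class PowerResult:
    gene: str
    margins: MarginSpec
    min_p: float
    corrected_min_p: float
    powered: bool


NOT_DETECTABLE = None  # sentinel returned by min_detectable_count


def min_achievable_p(margins: MarginSpec, sidedness: str = "two_sided") -> float:
    """Smallest Fisher P value over all tables with the given fixed margins.

    Scans every allocation a in [max(0, m-n2), min(m, n1)] of mutated
    samples to the exposed cohort and minimises the Fisher P of
    [[a, n1-a], [m-a, n2-m+a]].
    """
    _, pvals = fisher_pvalues_all_tables(margins.n1, margins.n2, margins.m, sidedness)
    return float(pvals.min())


def powered_genes(
    gene_margins: dict[str, MarginSpec], params: PowerParams
) -> list[PowerResult]:
    """Power gate over a gene panel, sorted by Bonferroni-corrected minimal P."""
    if not gene_margins:
        raise ValueError("gene_margins must be nonempty")
    results = []
    for gene, margins in gene_margins.items():
        mp = min_achievable_p(margins, params.sidedness)
        corrected = min(1.0, mp * params.n_tests)
        results.append(
            PowerResult(
                gene=gene,
                margins=margins,
                min_p=mp,
                corrected_min_p=corrected,
                powered=corrected < params.alpha,
            )
        )
    results.sort(key=lambda r: (r.corrected_min_p, r.gene))
    return results


def min_detectable_count(
    n1: int, n2: int, alpha: float = 0.05, max_observed: int = 0
) -> int | None:
    """Smallest control mutated count m making a one-sided deficit detectable.

    For each m the extreme table assigns ``max_observed`` mutated samples
    (default zero) to the exposed cohort: [[max_observed, n1 - max_observed],
    [m, n2 - m]].  Returns the smallest m whose one-sided (deficiency in the
    exposed group) Fisher P is below alpha, or None when no m on [0, n2]
    achieves it.  The one-sided P is nonincreasing in m, so the first
    crossing defines the answer.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("cohort sizes must be positive")
    if not (0 <= max_observed <= n1):
        raise ValueError("max_observed outside [0, n1]")
    for m in range(0, n2 + 1):
        table = [[max_observed, n1 - max_observed], [m, n2 - m]]
        p = fisher_2x2(table, "less").p_value
        if p < alpha:
            return m
    return NOT_DETECTABLE


def compare_gene_frequencies(
    exposed: Cohort,
    control: Cohort,
    genes: GeneList,
    params: PowerParams,
    hotspot_only: bool = False,
) -> pd.DataFrame:
    """Power-gated per-gene frequency comparison between two cohorts.

    Pipeline: (1) per-gene margins from the observed binarized cohorts,
    (2) power gate (minimal achievable P, Bonferroni over ``params.n_tests``),
    (3) Fisher test at the configured sidedness for powered genes only,
    (4) Benjamini-Hochberg across the powered genes.

    Returns a DataFrame with one row per gene: counts, frequencies with
    Beta-distribution SDs, power-gate quantities, P and Q (NaN for
    unpowered genes, which are never tested).
    """
    if not genes.genes:
        raise ValueError("empty gene list")
    mat1 = binarize(exposed, genes, hotspot_only=hotspot_only)
    mat2 = binarize(control, genes, hotspot_only=hotspot_only)
    n1, n2 = exposed.n_samples, control.n_samples
    rows = []
    for gene in genes.genes:
        k1 = int(mat1.loc[gene].sum())
        k2 = int(mat2.loc[gene].sum())
        margins = MarginSpec(n1=n1, n2=n2, m=k1 + k2)
        mp = min_achievable_p(margins, params.sidedness)
        corrected = min(1.0, mp * params.n_tests)
        powered = corrected < params.alpha
        p = np.nan
        if powered:
            p = fisher_2x2(
                [[k1, n1 - k1], [k2, n2 - k2]], params.sidedness
            ).p_value
        f1, f2 = FrequencyEstimate(k1, n1), FrequencyEstimate(k2, n2)
        rows.append(
            {
                "gene": gene,
                "k1": k1, "n1": n1, "freq1": f1.freq, "sd1": f1.sd,
                "k2": k2, "n2": n2, "freq2": f2.freq, "sd2": f2.sd,
                "min_p": mp, "corrected_min_p": corrected, "powered": powered,
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    df["q"] = np.nan
    mask = df["powered"] & df["p"].notna()
    if mask.any():
        df.loc[mask, "q"] = bh_adjust(df.loc[mask, "p"].to_numpy())
    return df.sort_values(["q", "p", "gene"], na_position="last").reset_index(drop=True)
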