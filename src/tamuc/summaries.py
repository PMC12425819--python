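"""Scalar summaries: mutational burden, SCNA fraction, ddPCR calls and the
expected number of background (tamoxifen-unrelated) cases.

The background-risk expectation divides the baseline 10-year uterine-cancer
risk by the risk under tamoxifen: with a fivefold risk increase
(0.5% -> 2.5%), one fifth of exposed-cohort cases are expected to be
coincidental, i.e. n x baseline/treated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .io import CopyNumberSegment

#: PIK3CA activating hotspots assayed by ddPCR.
DEFAULT_HOTSPOT_PANEL: Mapping[str, frozenset[str]] = {
    "PIK3CA": frozenset({"E542K", "E545K", "H1047R"})
}


@dataclass(frozen=True)
class DdpcrParams:
    """Droplet digital PCR calling parameters (allele fraction in percent)."""

    af_cutoff_percent: float = 2.0
    hotspot_panel: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_HOTSPOT_PANEL)
    )

    def __post_init__(self) -> None:
        if not (0.0 < self.af_cutoff_percent < 100.0):
            raise ValueError("af_cutoff_percent must be in (0, 100)")


@dataclass(frozen=True)
class RiskParams:
    """Absolute 10-year uterine-cancer risks without and with tamoxifen."""

    baseline_risk: float = 0.005
    treated_risk: float = 0.025

    def __post_init__(self) -> None:
        if not (0.0 < self.baseline_risk <= self.treated_risk < 1.0):
            raise ValueError("need 0 < baseline_risk <= treated_risk < 1")

    @property
    def fold(self) -> float:
        return self.treated_risk / self.baseline_risk


def mutation_burden(n_mutations: int, territory_mb: float) -> float:
    """Somatic mutations per megabase of sequenced territory."""
    if territory_mb <= 0:
        raise ValueError("territory_mb must be positive")
    if n_mutations < 0:
        raise ValueError("n_mutations must be nonnegative")
    return n_mutations / territory_mb


def scna_fraction(
    segments: Sequence[CopyNumberSegment],
    amplitude_threshold: float,
    territory: float,
) -> float:
    """Fraction of the territory altered by |copy-ratio change| >= threshold."""
    if territory <= 0:
        raise ValueError("territory must be positive")
    altered = sum(
        s.length for s in segments if abs(s.seg_value) >= amplitude_threshold
    )
    return min(1.0, altered / territory)


def ddpcr_af(n_mutant: int, n_wildtype: int) -> float:
    """Allele fraction in percent: mutant / (mutant + wild type) x 100."""
    if n_mutant < 0 or n_wildtype < 0:
        raise ValueError("droplet counts must be nonnegative")
    total = n_mutant + n_wildtype
    if total == 0:
        raise ValueError("zero total droplets")
    return 100.0 * n_mutant / total


def call_ddpcr(
    n_mutant: int, n_wildtype: int, params: DdpcrParams = DdpcrParams()
) -> str:
    """'positive' iff the allele fraction strictly exceeds the cutoff."""
    return "positive" if ddpcr_af(n_mutant, n_wildtype) > params.af_cutoff_percent \
        else "negative"


def expected_background_cases(
    n_exposed_cases: int, params: RiskParams = RiskParams()
) -> tuple[float, int]:
    """Expected tamoxifen-unrelated cases among the exposed-cohort patients.

    Returns (exact value, nearest-integer presentation value):
    n x baseline_risk / treated_risk.
    """
    if n_exposed_cases < 0:
        raise ValueError("n_exposed_cases must be nonnegative")
    value = n_exposed_cases * params.baseline_risk / params.treated_risk
    return value, round(value)
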