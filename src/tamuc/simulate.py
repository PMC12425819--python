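"""Seeded simulator of paired exposed/control uterine-cancer cohorts.

The generator plants the statistical structure the downstream analysis
assumes — per-gene mutated-sample probabilities, strata composition, purity,
per-subtype deleted-genome fractions, clonal/subclonal CCF mixtures,
signature-derived trinucleotide contexts, WGD multiplicities and ddPCR
droplet counts — so every stage of the pipeline is testable without any
cohort download.  Defaults mirror the motivating study design: 21 exposed
versus 554 control tumors, PIK3CA mutated in 14% versus 48% and PIK3R1 in
0% versus 31% of samples, a 37-Mb exome territory, and a subtype mix close
to the TCGA uterine-cancer distribution.

All draws flow through a single ``numpy`` Generator seeded once, so
sub-generators cannot silently desynchronize; identical configs and seeds
give byte-identical written fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    Cohort,
    CopyNumberSegment,
    GeneList,
    MutationRecord,
    SampleAnnotation,
)
from .stats import ContingencyTable
from .subtype import SBS96_CHANNELS, SignatureCatalog

#: The 13 COSMIC-v3 signature names the subtype cascade expects
#: (aging, MSI-associated, POLE-associated, APOBEC).
DEFAULT_SIGNATURES: tuple[str, ...] = (
    "SBS1", "SBS2", "SBS5", "SBS6", "SBS10a", "SBS10b", "SBS13",
    "SBS14", "SBS15", "SBS20", "SBS21", "SBS26", "SBS44",
)

DEFAULT_GENE_PROBS: Mapping[str, tuple[float, float]] = {
    # (p_exposed, p_control); PIK3CA/PIK3R1 frequencies are the study's
    # printed values, the rest are typical de novo UC driver frequencies.
    "PIK3CA": (0.14, 0.48),
    "PIK3R1": (0.00, 0.31),
    "PTEN": (0.67, 0.64),
    "TP53": (0.38, 0.36),
    "ARID1A": (0.43, 0.44),
    "KRAS": (0.24, 0.21),
    "CTNNB1": (0.19, 0.26),
}

_SUBTYPES = ("POLE", "MSI", "CIN", "GS")

DEFAULT_SIGNATURE_WEIGHTS: Mapping[str, Mapping[str, float]] = {
    "POLE": {"SBS10a": 0.55, "SBS10b": 0.25, "SBS14": 0.05, "SBS1": 0.05, "SBS5": 0.10},
    "MSI": {"SBS6": 0.35, "SBS15": 0.15, "SBS21": 0.10, "SBS26": 0.10, "SBS44": 0.15,
            "SBS1": 0.05, "SBS5": 0.10},
    "CIN": {"SBS1": 0.35, "SBS5": 0.45, "SBS2": 0.10, "SBS13": 0.10},
    "GS": {"SBS1": 0.40, "SBS5": 0.60},
}

#: hotspot protein changes planted on PIK3CA-mutated samples
PIK3CA_HOTSPOTS = ("E542K", "E545K", "H1047R")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one paired-cohort simulation."""

    n_exposed: int = 21
    n_control: int = 554
    gene_probs: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GENE_PROBS)
    )
    #: stratum label -> sampling weight, per cohort (grade composition differs)
    strata_exposed: Mapping[str, float] = field(
        default_factory=lambda: {"low_grade": 0.4, "high_grade": 0.6}
    )
    strata_control: Mapping[str, float] = field(
        default_factory=lambda: {"low_grade": 0.6, "high_grade": 0.4}
    )
    purity_bounds: tuple[float, float] = (0.3, 0.9)
    #: proportions over (POLE, MSI, CIN, GS), same in both cohorts
    subtype_mix: tuple[float, float, float, float] = (0.07, 0.28, 0.26, 0.39)
    #: per-subtype deleted-genome-fraction bounds
    deleted_fraction_bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "POLE": (0.0, 0.02), "MSI": (0.0, 0.02),
            "CIN": (0.06, 0.40), "GS": (0.0, 0.02),
        }
    )
    #: background somatic burden in mutations per Mb, per-subtype multiplier
    burden_per_mb: float = 2.3
    burden_multiplier: Mapping[str, float] = field(
        default_factory=lambda: {"POLE": 10.0, "MSI": 4.0, "CIN": 1.0, "GS": 1.0}
    )
    territory_mb: float = 37.0
    genome_mb: float = 3000.0
    clonal_prob: float = 0.8
    ccf_noise_sd: float = 0.02
    subclonal_bounds: tuple[float, float] = (0.1, 0.7)
    wgd_prob: float = 0.25
    pre_wgd_prob: float = 0.6
    hotspot_fraction: float = 0.79  # of PIK3CA-mutated samples carrying a hotspot
    signature_weights: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SIGNATURE_WEIGHTS.items()}
    )
    ddpcr_droplets: int = 10_000
    ddpcr_positive_af: float = 0.05
    ddpcr_false_rate: float = 0.0005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_exposed < 1 or self.n_control < 1:
            raise ValueError("cohort sizes must be >= 1")
        for gene, (p1, p2) in self.gene_probs.items():
            if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
                raise ValueError(f"probabilities for {gene} outside [0, 1]")
        if abs(sum(self.subtype_mix) - 1.0) > 1e-9:
            raise ValueError("subtype_mix must sum to 1")
        for weights in (self.strata_exposed, self.strata_control):
            if not weights or any(w < 0 for w in weights.values()):
                raise ValueError("strata weights must be nonnegative and nonempty")


# ---------------------------------------------------------------------------
# Catalog and low-level draws
# ---------------------------------------------------------------------------


def synthetic_catalog(
    names: Sequence[str] = DEFAULT_SIGNATURES, seed: int = 0, concentration: float = 0.1
) -> SignatureCatalog:
    """A synthetic 96-channel signature catalog (Dirichlet-random columns).

    Stand-in for the COSMIC v3 profiles, which are an input file in real
    runs; sparse Dirichlet columns are mutually distinguishable, which is
    all the cascade's presence/absence decisions require.  Deterministic
    given the seed.
    """
    rng = np.random.default_rng(seed)
    profiles = rng.dirichlet([concentration] * 96, size=len(names)).T
    profiles /= profiles.sum(axis=0, keepdims=True)
    return SignatureCatalog(names=tuple(names), profiles=profiles)


def simulate_table(
    n1: int, n2: int, p1: float, p2: float, seed: int | None = None
) -> ContingencyTable:
    """Binomial 2x2 cohort table: [[k1, n1-k1], [k2, n2-k2]]."""
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    k1 = int(rng.binomial(n1, p1))
    k2 = int(rng.binomial(n2, p2))
    return ContingencyTable(
        counts=np.array([[k1, n1 - k1], [k2, n2 - k2]]),
        row_labels=("exposed", "control"),
        col_labels=("mutated", "wildtype"),
    )


def simulate_ccfs(
    n_clonal: int,
    n_subclonal: int,
    noise_sd: float = 0.02,
    seed: int | None = None,
    subclonal_bounds: tuple[float, float] = (0.1, 0.7),
) -> list[float]:
    """Planted CCFs: clonal values hug 1 from below, subclonal stay < 0.95.

    Clonal: min(1, 1 - |N(0, noise_sd)|), clipped into the clonal band
    [0.95, 1] so planted-clonal mutations satisfy the CCF >= 0.95 rule by
    construction; subclonal: uniform on the given sub-unit bounds (below the
    clonal threshold with margin).  Order is randomized.
    """
    if n_clonal < 0 or n_subclonal < 0:
        raise ValueError("counts must be nonnegative")
    lo, hi = subclonal_bounds
    if not (0.0 <= lo <= hi < 0.95):
        raise ValueError("subclonal bounds must lie within [0, 0.95)")
    rng = np.random.default_rng(seed)
    clonal = np.clip(1.0 - np.abs(rng.normal(0.0, noise_sd, n_clonal)), 0.95, 1.0)
    subclonal = rng.uniform(lo, hi, n_subclonal)
    ccfs = np.concatenate([clonal, subclonal])
    rng.shuffle(ccfs)
    return [float(c) for c in ccfs]


def simulate_counts96(
    catalog: SignatureCatalog,
    weights: Mapping[str, float] | Sequence[float],
    total: int,
    seed: int | None = None,
) -> np.ndarray:
    """Multinomial 96-channel counts from a signature mixture."""
    if isinstance(weights, Mapping):
        w = np.array([weights.get(name, 0.0) for name in catalog.names])
    else:
        w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if w.sum() == 0:
        raise ValueError("all-zero signature weights")
    if total < 0:
        raise ValueError("total must be nonnegative")
    probs = catalog.profiles @ (w / w.sum())
    probs /= probs.sum()
    rng = np.random.default_rng(seed)
    return rng.multinomial(total, probs)


def simulate_segments(
    target_deleted_fraction: float,
    purity: float,
    genome_mb: float = 3000.0,
    seed: int | None = None,
    n_segments: int = 100,
    r1: float = 0.36,
    sample_id: str = "S",
) -> list[CopyNumberSegment]:
    """Segments whose deleted fraction matches the target within granularity.

    The genome is tiled with equal segments (granularity genome/n_segments);
    round(target * n_segments) of them, at shuffled positions, carry a
    copy-ratio change clearly below -r1 x purity, the rest stay strictly
    inside the neutral band.
    """
    if not (0.0 <= target_deleted_fraction <= 1.0):
        raise ValueError("target fraction outside [0, 1]")
    rng = np.random.default_rng(seed)
    n_del = round(target_deleted_fraction * n_segments)
    deleted_idx = set(rng.choice(n_segments, size=n_del, replace=False).tolist())
    seg_len_kb = int(genome_mb * 1000 / n_segments)
    threshold = r1 * purity
    segs = []
    for i in range(n_segments):
        start = i * seg_len_kb + 1
        if i in deleted_idx:
            value = -(threshold * float(rng.uniform(1.3, 2.0)))
        else:
            value = float(rng.uniform(-0.5, 0.5)) * threshold
        segs.append(
            CopyNumberSegment(
                sample_id=sample_id,
                chromosome="1",
                start=start,
                end=start + seg_len_kb - 1,
                seg_value=value,
            )
        )
    return segs


def simulate_ddpcr_wells(
    n_positive: int,
    n_negative: int,
    droplets: int = 10_000,
    positive_af: float = 0.05,
    false_rate: float = 0.0005,
    seed: int | None = None,
    assay: str = "PIK3CA_hotspot",
) -> pd.DataFrame:
    """Per-well mutant/wild-type droplet counts for a hotspot assay.

    Positive wells draw mutant droplets at the planted allele fraction;
    negative wells at a small FFPE-like false-positive rate.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_positive + n_negative):
        af = positive_af if i < n_positive else false_rate
        n_mut = int(rng.binomial(droplets, af))
        rows.append(
            {
                "sample": f"W{i:03d}",
                "assay": assay,
                "mutant_droplets": n_mut,
                "wildtype_droplets": droplets - n_mut,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full cohort-pair simulation
# ---------------------------------------------------------------------------

_GENE_META = {
    # chromosome, representative position, generic (non-hotspot) protein change
    "PIK3CA": ("3", 178936091, "R88Q"),
    "PIK3R1": ("5", 67589139, "G376R"),
    "PTEN": ("10", 89692905, "R130Q"),
    "TP53": ("17", 7577121, "R273H"),
    "ARID1A": ("1", 27099423, "Q456*"),
    "KRAS": ("12", 25398284, "G12D"),
    "CTNNB1": ("3", 41266101, "S37F"),
    "POLE": ("12", 133250250, "P286R"),
}


def _channel_to_snv(channel: str) -> tuple[str, str, str]:
    """(ref, alt, trinucleotide context) for an SBS96 channel label."""
    five, rest = channel[0], channel[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    return ref, alt, f"{five}{ref}{three}"


def _draw_ccf_mult(rng, config: SimConfig, wgd: bool) -> tuple[float, int]:
    if rng.uniform() < config.clonal_prob:
        # clipped into the clonal band so planted-clonal stays clonal
        ccf = float(np.clip(1.0 - abs(rng.normal(0.0, config.ccf_noise_sd)),
                            0.95, 1.0))
        clonal = True
    else:
        lo, hi = config.subclonal_bounds
        ccf = float(rng.uniform(lo, hi))
        clonal = False
    if wgd and clonal and rng.uniform() < config.pre_wgd_prob:
        mult = 2
    else:
        mult = 1
    return ccf, mult


def _simulate_one_cohort(
    config: SimConfig,
    rng: np.random.Generator,
    cohort_label: str,
    catalog: SignatureCatalog,
) -> tuple[Cohort, dict[str, str]]:
    n = config.n_exposed if cohort_label == "exposed" else config.n_control
    strata = (
        config.strata_exposed if cohort_label == "exposed" else config.strata_control
    )
    stratum_labels = sorted(strata)
    stratum_w = np.array([strata[s] for s in stratum_labels], dtype=float)
    stratum_w /= stratum_w.sum()
    prefix = "TA" if cohort_label == "exposed" else "DN"
    gene_p_index = 0 if cohort_label == "exposed" else 1

    annotations: list[SampleAnnotation] = []
    mutations: list[MutationRecord] = []
    segments: list[CopyNumberSegment] = []
    planted: dict[str, str] = {}
    channel_labels = np.array(SBS96_CHANNELS)

    for i in range(n):
        sid = f"{prefix}{i:04d}"
        grade = stratum_labels[int(rng.choice(len(stratum_labels), p=stratum_w))]
        purity = float(rng.uniform(*config.purity_bounds))
        subtype = _SUBTYPES[int(rng.choice(4, p=np.asarray(config.subtype_mix)))]
        planted[sid] = subtype
        wgd = bool(rng.uniform() < config.wgd_prob)
        annotations.append(
            SampleAnnotation(
                sample_id=sid,
                cohort=cohort_label,
                purity=purity,
                ploidy=3.8 if wgd else 2.0,
                wgd=wgd,
                histology="endometrioid",
                grade=grade,
                tamoxifen_years=float(rng.uniform(2, 10))
                if cohort_label == "exposed" else None,
                msi_flag=(subtype == "MSI"),
            )
        )

        # context mixture for this sample's subtype
        weights = config.signature_weights[subtype]
        wvec = np.array([weights.get(nm, 0.0) for nm in catalog.names])
        probs = catalog.profiles @ (wvec / wvec.sum())
        probs /= probs.sum()

        def _context() -> tuple[str, str, str]:
            ch = channel_labels[int(rng.choice(96, p=probs))]
            return _channel_to_snv(str(ch))

        # driver-gene indicators
        for gene, p_pair in config.gene_probs.items():
            if rng.uniform() >= p_pair[gene_p_index]:
                continue
            chrom, pos, generic_pc = _GENE_META.get(gene, ("1", 1_000_000, "A100V"))
            if gene == "PIK3CA" and rng.uniform() < config.hotspot_fraction:
                pc = str(PIK3CA_HOTSPOTS[int(rng.choice(3))])
            else:
                pc = generic_pc
            ccf, mult = _draw_ccf_mult(rng, config, wgd)
            ref, alt, ctx = _context()
            mutations.append(
                MutationRecord(
                    sample_id=sid,
                    gene=gene,
                    chromosome=chrom,
                    start=pos,
                    ref_allele=ref,
                    alt_allele=alt,
                    variant_classification="Missense_Mutation"
                    if not pc.endswith("*") else "Nonsense_Mutation",
                    protein_change=f"p.{pc}",
                    protein_position=int("".join(c for c in pc[1:] if c.isdigit())),
                    trinucleotide_context=ctx,
                    ccf=ccf,
                    multiplicity=mult,
                )
            )

        # POLE subtype needs an exonuclease-domain mutation
        if subtype == "POLE":
            ccf, mult = _draw_ccf_mult(rng, config, wgd)
            ref, alt, ctx = _context()
            mutations.append(
                MutationRecord(
                    sample_id=sid, gene="POLE", chromosome="12", start=133250250,
                    ref_allele=ref, alt_allele=alt,
                    variant_classification="Missense_Mutation",
                    protein_change="p.P286R", protein_position=286,
                    trinucleotide_context=ctx, ccf=ccf, multiplicity=mult,
                )
            )

        # background passengers at the subtype-scaled burden
        lam = config.burden_per_mb * config.burden_multiplier[subtype] * config.territory_mb
        n_bg = int(rng.poisson(lam))
        bg_channels = rng.choice(96, size=n_bg, p=probs)
        for j, ch_idx in enumerate(bg_channels):
            ref, alt, ctx = _channel_to_snv(SBS96_CHANNELS[int(ch_idx)])
            ccf, mult = _draw_ccf_mult(rng, config, wgd)
            mutations.append(
                MutationRecord(
                    sample_id=sid,
                    gene=f"PSG{int(rng.integers(1, 5000)):04d}",
                    chromosome=str(int(rng.integers(1, 23))),
                    start=int(rng.integers(1, 200_000_000)),
                    ref_allele=ref,
                    alt_allele=alt,
                    variant_classification="Missense_Mutation"
                    if rng.uniform() > 0.15 else "Silent",
                    trinucleotide_context=ctx,
                    ccf=ccf,
                    multiplicity=mult,
                )
            )

        lo, hi = config.deleted_fraction_bounds[subtype]
        target = float(rng.uniform(lo, hi))
        segments.extend(
            simulate_segments(
                target, purity, config.genome_mb,
                seed=int(rng.integers(0, 2**31 - 1)), sample_id=sid,
            )
        )

    cohort = Cohort(
        annotations=annotations,
        mutations=mutations,
        segments=segments,
        territory_mb=config.territory_mb,
    )
    return cohort, planted


def simulate_cohort_pair(
    config: SimConfig | None = None,
    catalog: SignatureCatalog | None = None,
    with_truth: bool = False,
):
    """Simulate the (exposed, control) cohort pair under the study conditions.

    Fully reproducible: all randomness flows through one generator seeded
    with ``config.seed``; the catalog (if not supplied) is derived from the
    same seed.  With ``with_truth`` a third element maps each sample to its
    planted molecular subtype (generator bookkeeping for validation).
    """
    config = config or SimConfig()
    if not config.gene_probs:
        raise ValueError("gene_probs must be nonempty")
    rng = np.random.default_rng(config.seed)
    catalog = catalog or synthetic_catalog(seed=config.seed)
    exposed, truth_e = _simulate_one_cohort(config, rng, "exposed", catalog)
    control, truth_c = _simulate_one_cohort(config, rng, "control", catalog)
    if with_truth:
        return exposed, control, {**truth_e, **truth_c}
    return exposed, control


def default_driver_panel() -> GeneList:
    """Driver panel matching the simulator's planted genes, with hotspots."""
    return GeneList(
        name="uc_drivers",
        genes=tuple(DEFAULT_GENE_PROBS),
        hotspots={"PIK3CA": frozenset(PIK3CA_HOTSPOTS)},
    )
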