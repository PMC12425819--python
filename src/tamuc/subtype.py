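"""TCGA-style molecular-subtype cascade for uterine cancer samples.

Samples are classified in a fixed order: POLE (ultramutated) first, then MSI
(hypermutated), then CIN versus GS by copy-number pattern.

* POLE: at least one nonsynonymous POLE mutation in the exonuclease domain
  (protein positions 268-471) AND a sufficient summed exposure fraction of
  the POLE-associated signatures (SBS10a, SBS10b, SBS14).
* MSI: an upstream MSI call when available (flag on the sample annotation);
  otherwise a sufficient summed fraction of the MSI-associated signatures
  (SBS6, SBS14, SBS15, SBS20, SBS21, SBS26, SBS44).
* CIN vs GS: the fraction of the genome deleted beyond an amplitude
  threshold of R1 = 0.36 copy-ratio units.  Apparent amplitude shrinks in
  impure samples, so the effective threshold is R1 x purity.  Samples whose
  deleted-genome fraction exceeds R2 = 0.034 are CIN, the rest GS.

Signature exposures are obtained by nonnegative least squares against a
fixed 96-channel catalog: deterministic, and sufficient for the cascade's
presence/absence decisions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .io import CopyNumberSegment, MutationRecord, SampleAnnotation, filter_nonsynonymous

logger = logging.getLogger(__name__)

_SUBS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"

#: Fixed ordering of the 96 single-base-substitution channels
#: (pyrimidine-strand convention, grouped by substitution type).
SBS96_CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}" for sub in _SUBS for five in _BASES for three in _BASES
)
_CHANNEL_INDEX = {c: i for i, c in enumerate(SBS96_CHANNELS)}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SignatureCatalog:
    """Named 96-channel signature profiles; each column sums to one."""

    names: tuple[str, ...]
    profiles: np.ndarray  # shape (96, n_signatures)

    def __post_init__(self) -> None:
        arr = np.asarray(self.profiles, dtype=float)
        if arr.shape != (96, len(self.names)):
            raise ValueError(
                f"profiles shape {arr.shape} inconsistent with "
                f"{len(self.names)} signature name(s)"
            )
        if np.any(arr < 0):
            raise ValueError("signature profiles must be nonnegative")
        sums = arr.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("each signature column must sum to 1")
        object.__setattr__(self, "profiles", arr)
        object.__setattr__(self, "names", tuple(self.names))

    @classmethod
    def from_tsv(cls, path) -> "SignatureCatalog":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df = df.reindex(list(SBS96_CHANNELS))
        if df.isna().any().any():
            raise ValueError(f"{path}: missing or unknown channel labels")
        return cls(names=tuple(df.columns), profiles=df.to_numpy())

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            self.profiles, index=list(SBS96_CHANNELS), columns=list(self.names)
        ).to_csv(path, sep="\t", index_label="channel", lineterminator="\n")


POLE_SIGNATURES = frozenset({"SBS10a", "SBS10b", "SBS14"})
MSI_SIGNATURES = frozenset({"SBS6", "SBS14", "SBS15", "SBS20", "SBS21", "SBS26", "SBS44"})


@dataclass(frozen=True)
class SubtypeParams:
    """Thresholds of the subtype cascade.

    r1: copy-ratio amplitude defining a deletion (scaled by purity).
    r2: deleted-genome fraction separating CIN from GS.
    signature_fraction_threshold: minimum summed exposure fraction counted
        as signature evidence for the POLE / MSI branches.
    purity_scales_threshold: if False, the amplitude threshold is divided by
        purity instead of multiplied (the alternative reading).
    """

    r1: float = 0.36
    r2: float = 0.034
    pole_signatures: frozenset[str] = POLE_SIGNATURES
    msi_signatures: frozenset[str] = MSI_SIGNATURES
    pole_domain: tuple[int, int] = (268, 471)
    signature_fraction_threshold: float = 0.2
    purity_scales_threshold: bool = True

    def __post_init__(self) -> None:
        if self.r1 <= 0 or self.r2 <= 0:
            raise ValueError("r1 and r2 must be positive")
        if not (0.0 < self.signature_fraction_threshold < 1.0):
            raise ValueError("signature_fraction_threshold must be in (0, 1)")


@dataclass(frozen=True)
class SubtypeCall:
    sample_id: str
    subtype: str  # POLE | MSI | CIN | GS
    pole_domain_mutation: bool = False
    pole_fraction: float = 0.0
    msi_source: str = "none"  # flag | signature | none
    msi_fraction: float = 0.0
    deleted_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.subtype not in ("POLE", "MSI", "CIN", "GS"):
            raise ValueError(f"unknown subtype {self.subtype!r}")


# ---------------------------------------------------------------------------
# SBS96 counting and exposure fitting
# ---------------------------------------------------------------------------


def sbs96_vector(records: Sequence[MutationRecord]) -> np.ndarray:
    """Count SNVs into the 96 substitution-in-context channels.

    Purine-reference records are collapsed to the pyrimidine strand by
    reverse complementing the context and both alleles.  Records that are
    not SNVs or lack a context are skipped (count logged); a context whose
    middle base contradicts the reference allele raises.
    """
    counts = np.zeros(96, dtype=np.int64)
    skipped = 0
    for rec in records:
        if not rec.is_snv or not rec.trinucleotide_context:
            skipped += 1
            continue
        ctx = rec.trinucleotide_context.upper()
        if len(ctx) != 3 or any(b not in _BASES for b in ctx):
            raise ValueError(f"malformed trinucleotide context {ctx!r}")
        ref, alt = rec.ref_allele, rec.alt_allele
        if ctx[1] != ref:
            raise ValueError(
                f"context {ctx} middle base inconsistent with ref allele {ref}"
            )
        if ref in "AG":  # collapse to pyrimidine strand
            ctx = _revcomp(ctx)
            ref = ref.translate(_COMPLEMENT)
            alt = alt.translate(_COMPLEMENT)
        counts[_CHANNEL_INDEX[f"{ctx[0]}[{ref}>{alt}]{ctx[2]}"]] += 1
    if skipped:
        logger.info("sbs96_vector: skipped %d non-SNV/contextless record(s)", skipped)
    return counts


def nnls_exposures(counts96: np.ndarray, catalog: SignatureCatalog) -> np.ndarray:
    """Nonnegative least-squares signature exposures (in mutation counts)."""
    counts = np.asarray(counts96, dtype=float)
    if counts.shape != (96,):
        raise ValueError(f"expected a 96-vector, got shape {counts.shape}")
    if counts.sum() == 0:
        warnings.warn("zero mutation counts; exposures are all zero", stacklevel=2)
        return np.zeros(len(catalog.names))
    exposures, _ = nnls(catalog.profiles, counts)
    return exposures


def signature_fractions(
    exposures: np.ndarray, catalog: SignatureCatalog, total_count: float
) -> dict[str, float]:
    """Exposure fractions per signature, normalized by the total SNV count.

    Fractions sum to at most 1 (the NNLS fit may not reconstruct all
    counts exactly).
    """
    if total_count <= 0:
        return {name: 0.0 for name in catalog.names}
    return {
        name: float(e) / float(total_count)
        for name, e in zip(catalog.names, exposures)
    }


# ---------------------------------------------------------------------------
# Cascade branches
# ---------------------------------------------------------------------------


def classify_pole(
    mutations: Sequence[MutationRecord],
    fractions: Mapping[str, float],
    params: SubtypeParams = SubtypeParams(),
) -> bool:
    """POLE branch: exonuclease-domain mutation AND POLE-signature evidence."""
    lo, hi = params.pole_domain
    domain_hit = any(
        r.gene == "POLE"
        and r.protein_position is not None
        and lo <= r.protein_position <= hi
        for r in filter_nonsynonymous(mutations)
    )
    pole_frac = sum(fractions.get(s, 0.0) for s in params.pole_signatures)
    return domain_hit and pole_frac >= params.signature_fraction_threshold


def classify_msi(
    annotation: SampleAnnotation,
    fractions: Mapping[str, float],
    params: SubtypeParams = SubtypeParams(),
) -> bool:
    """MSI branch: upstream flag when present, else signature evidence."""
    if annotation.msi_flag is not None:
        return annotation.msi_flag
    msi_frac = sum(fractions.get(s, 0.0) for s in params.msi_signatures)
    return msi_frac >= params.signature_fraction_threshold


def deleted_genome_fraction(
    segments: Sequence[CopyNumberSegment],
    purity: float,
    params: SubtypeParams = SubtypeParams(),
    territory: float | None = None,
) -> float:
    """Fraction of covered genome deleted beyond the purity-scaled threshold.

    A segment counts as deleted when its copy-ratio change is at or below
    -r1 x purity (boundary inclusive).  The denominator is the total length
    covered by segments unless an explicit territory is given (same units
    as segment coordinates).
    """
    if not (0.0 < purity <= 1.0):
        raise ValueError(f"purity {purity} outside (0, 1]")
    total = territory if territory is not None else sum(s.length for s in segments)
    if total is None or total <= 0:
        raise ValueError("zero covered territory")
    threshold = params.r1 * purity if params.purity_scales_threshold else params.r1 / purity
    deleted = sum(s.length for s in segments if s.seg_value <= -threshold)
    return min(1.0, deleted / total)


def classify_subtype(
    sample_id: str,
    mutations: Sequence[MutationRecord],
    segments: Sequence[CopyNumberSegment],
    annotation: SampleAnnotation,
    catalog: SignatureCatalog,
    params: SubtypeParams = SubtypeParams(),
    territory: float | None = None,
    counts96: np.ndarray | None = None,
) -> SubtypeCall:
    """Full cascade: POLE, else MSI, else CIN/GS by deleted-genome fraction."""
    if counts96 is None:
        counts96 = sbs96_vector(mutations)
    total = float(np.asarray(counts96).sum())
    if total > 0:
        exposures = nnls_exposures(counts96, catalog)
    else:
        exposures = np.zeros(len(catalog.names))
    fractions = signature_fractions(exposures, catalog, total)
    pole_frac = sum(fractions.get(s, 0.0) for s in params.pole_signatures)
    msi_frac = sum(fractions.get(s, 0.0) for s in params.msi_signatures)
    lo, hi = params.pole_domain
    domain_hit = any(
        r.gene == "POLE"
        and r.protein_position is not None
        and lo <= r.protein_position <= hi
        for r in filter_nonsynonymous(mutations)
    )
    deleted = deleted_genome_fraction(segments, annotation.purity, params, territory) \
        if segments else 0.0

    if domain_hit and pole_frac >= params.signature_fraction_threshold:
        subtype = "POLE"
        msi_source = "none"
    elif classify_msi(annotation, fractions, params):
        subtype = "MSI"
        msi_source = "flag" if annotation.msi_flag is not None else "signature"
    else:
        subtype = "CIN" if deleted > params.r2 else "GS"
        msi_source = "flag" if annotation.msi_flag is not None else "none"
    return SubtypeCall(
        sample_id=sample_id,
        subtype=subtype,
        pole_domain_mutation=domain_hit,
        pole_fraction=pole_frac,
        msi_source=msi_source,
        msi_fraction=msi_frac,
        deleted_fraction=deleted,
    )


def classify_cohort(cohort, catalog: SignatureCatalog,
                    params: SubtypeParams = SubtypeParams()) -> pd.DataFrame:
    """Apply the cascade to every sample of a cohort; returns a tidy table."""
    rows = []
    for ann in cohort.annotations:
        call = classify_subtype(
            ann.sample_id,
            cohort.mutations_of(ann.sample_id),
            cohort.segments_of(ann.sample_id),
            ann,
            catalog,
            params,
        )
        rows.append(
            {
                "sample_id": call.sample_id,
                "subtype": call.subtype,
                "pole_domain_mutation": call.pole_domain_mutation,
                "pole_fraction": call.pole_fraction,
                "msi_source": call.msi_source,
                "msi_fraction": call.msi_fraction,
                "deleted_fraction": call.deleted_fraction,
            }
        )
    return pd.DataFrame(rows)
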