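"""Data model and tabular I/O for two-cohort somatic-mutation studies.

Three tab-separated dialects are read and written:

* MAF-style mutation tables (one somatic variant per row),
* SEG-style copy-number segment tables (one genomic interval per row),
* per-sample annotation tables (cohort label, purity, strata, ...).

All coordinates are 1-based with inclusive ends, the community convention for
these formats.  Files are UTF-8 with Unix newlines and a mandatory header row.
Segment values are signed copy-ratio changes relative to the sample baseline
(linear scale, not log2), because the subtype thresholds are applied on that
scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Controlled vocabulary of variant classifications (MAF dialect).
VARIANT_CLASSIFICATIONS = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Frame_Shift_Ins",
        "Frame_Shift_Del",
        "In_Frame_Ins",
        "In_Frame_Del",
        "Splice_Site",
        "Nonstop_Mutation",
        "Translation_Start_Site",
        "Silent",
        "3'UTR",
        "5'UTR",
        "IGR",
        "Intron",
        "lincRNA",
        "RNA",
    }
)

#: Classifications removed by the nonsynonymous filter.
NONCODING_CLASSES = frozenset(
    {"3'UTR", "5'UTR", "IGR", "Intron", "lincRNA", "RNA", "Silent"}
)

COHORT_LABELS = ("exposed", "control")


class FormatError(ValueError):
    """A table file violates its dialect (missing column, bad value...)."""


@dataclass(frozen=True)
class MutationRecord:
    """One somatic variant in one sample."""

    sample_id: str
    gene: str
    chromosome: str
    start: int
    ref_allele: str
    alt_allele: str
    variant_classification: str
    protein_change: str | None = None
    protein_position: int | None = None
    trinucleotide_context: str | None = None
    ccf: float | None = None
    multiplicity: int | None = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.variant_classification not in VARIANT_CLASSIFICATIONS:
            raise ValueError(
                f"unknown variant_classification {self.variant_classification!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref_allele must differ from alt_allele")
        if self.ccf is not None and not (0.0 <= self.ccf <= 1.0):
            raise ValueError(f"ccf {self.ccf} outside [0, 1]")
        if self.multiplicity is not None and self.multiplicity < 1:
            raise ValueError("multiplicity must be a positive integer")

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref_allele) == 1
            and len(self.alt_allele) == 1
            and self.ref_allele in "ACGT"
            and self.alt_allele in "ACGT"
        )


@dataclass(frozen=True)
class CopyNumberSegment:
    """A genomic interval with a signed copy-ratio change for one sample."""

    sample_id: str
    chromosome: str
    start: int
    end: int
    seg_value: float
    n_probes: int | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid segment coordinates {self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SampleAnnotation:
    """Per-sample metadata: cohort label, purity, strata, treatment."""

    sample_id: str
    cohort: str
    purity: float = 1.0
    ploidy: float | None = None
    wgd: bool | None = None
    histology: str | None = None
    grade: str | None = None
    tamoxifen_years: float | None = None
    msi_flag: bool | None = None
    bmi: float | None = None

    def __post_init__(self) -> None:
        if self.cohort not in COHORT_LABELS:
            raise ValueError(
                f"cohort must be one of {COHORT_LABELS}, got {self.cohort!r}"
            )
        if not (0.0 < self.purity <= 1.0):
            raise ValueError(f"purity {self.purity} outside (0, 1]")
        if self.tamoxifen_years is not None and self.tamoxifen_years < 0:
            raise ValueError("tamoxifen_years must be nonnegative")


@dataclass
class Cohort:
    """A set of samples with their mutations and copy-number segments."""

    annotations: list[SampleAnnotation]
    mutations: list[MutationRecord] = field(default_factory=list)
    segments: list[CopyNumberSegment] = field(default_factory=list)
    territory_mb: float = 37.0  # exome coding territory

    def __post_init__(self) -> None:
        if self.territory_mb <= 0:
            raise ValueError("territory_mb must be positive")
        known = {a.sample_id for a in self.annotations}
        for rec in self.mutations:
            if rec.sample_id not in known:
                raise ValueError(f"mutation sample {rec.sample_id!r} not annotated")
        for seg in self.segments:
            if seg.sample_id not in known:
                raise ValueError(f"segment sample {seg.sample_id!r} not annotated")

    @property
    def sample_ids(self) -> list[str]:
        return [a.sample_id for a in self.annotations]

    @property
    def n_samples(self) -> int:
        return len(self.annotations)

    def mutations_of(self, sample_id: str) -> list[MutationRecord]:
        return [m for m in self.mutations if m.sample_id == sample_id]

    def segments_of(self, sample_id: str) -> list[CopyNumberSegment]:
        return [s for s in self.segments if s.sample_id == sample_id]

    def annotation_of(self, sample_id: str) -> SampleAnnotation:
        for a in self.annotations:
            if a.sample_id == sample_id:
                return a
        raise KeyError(sample_id)


@dataclass(frozen=True)
class GeneList:
    """Ordered unique gene symbols, optionally with per-gene hotspot changes."""

    name: str
    genes: tuple[str, ...]
    hotspots: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene symbols in gene list")
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(
            self,
            "hotspots",
            {g: frozenset(v) for g, v in dict(self.hotspots).items()},
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_MAF_REQUIRED = {
    "sample_id": "Tumor_Sample_Barcode",
    "gene": "Hugo_Symbol",
    "chromosome": "Chromosome",
    "start": "Start_Position",
    "ref_allele": "Reference_Allele",
    "alt_allele": "Tumor_Seq_Allele2",
    "variant_classification": "Variant_Classification",
}
_MAF_OPTIONAL = {
    "protein_change": "Protein_Change",
    "protein_position": "Protein_Position",
    "trinucleotide_context": "Trinucleotide_Context",
    "ccf": "CCF",
    "multiplicity": "Multiplicity",
}


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def _opt(value, cast):
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return cast(value)


def read_maf(path) -> list[MutationRecord]:
    """Read a MAF-style TSV into mutation records.

    Duplicate records (same sample, gene, position, alt allele) are collapsed
    with a logged warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    _require_columns(df, _MAF_REQUIRED.values(), path)
    records: list[MutationRecord] = []
    seen: set[tuple] = set()
    n_dup = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, row))
        try:
            start = int(row[_MAF_REQUIRED["start"]])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: line {i}: unparseable position "
                              f"{row[_MAF_REQUIRED['start']]!r}") from exc
        try:
            rec = MutationRecord(
                sample_id=row[_MAF_REQUIRED["sample_id"]],
                gene=row[_MAF_REQUIRED["gene"]],
                chromosome=str(row[_MAF_REQUIRED["chromosome"]]),
                start=start,
                ref_allele=row[_MAF_REQUIRED["ref_allele"]],
                alt_allele=row[_MAF_REQUIRED["alt_allele"]],
                variant_classification=row[_MAF_REQUIRED["variant_classification"]],
                protein_change=_opt(row.get(_MAF_OPTIONAL["protein_change"]), str),
                protein_position=_opt(
                    row.get(_MAF_OPTIONAL["protein_position"]), lambda v: int(float(v))
                ),
                trinucleotide_context=_opt(
                    row.get(_MAF_OPTIONAL["trinucleotide_context"]), str
                ),
                ccf=_opt(row.get(_MAF_OPTIONAL["ccf"]), float),
                multiplicity=_opt(
                    row.get(_MAF_OPTIONAL["multiplicity"]), lambda v: int(float(v))
                ),
            )
        except ValueError as exc:
            raise FormatError(f"{path}: line {i}: {exc}") from exc
        key = (rec.sample_id, rec.gene, rec.start, rec.alt_allele)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        records.append(rec)
    if n_dup:
        logger.warning("%s: collapsed %d duplicate mutation record(s)", path, n_dup)
    return records


def write_maf(records: Sequence[MutationRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "Hugo_Symbol": r.gene,
                "Chromosome": r.chromosome,
                "Start_Position": r.start,
                "Reference_Allele": r.ref_allele,
                "Tumor_Seq_Allele2": r.alt_allele,
                "Variant_Classification": r.variant_classification,
                "Tumor_Sample_Barcode": r.sample_id,
                "Protein_Change": r.protein_change,
                "Protein_Position": r.protein_position,
                "Trinucleotide_Context": r.trinucleotide_context,
                "CCF": r.ccf,
                "Multiplicity": r.multiplicity,
            }
        )
    cols = [
        "Hugo_Symbol", "Chromosome", "Start_Position", "Reference_Allele",
        "Tumor_Seq_Allele2", "Variant_Classification", "Tumor_Sample_Barcode",
        "Protein_Change", "Protein_Position", "Trinucleotide_Context", "CCF",
        "Multiplicity",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False,
                                            lineterminator="\n")


_SEG_COLS = ["Sample", "Chromosome", "Start", "End", "Num_Probes", "Segment_Mean"]


def read_seg(path) -> list[CopyNumberSegment]:
    """Read a SEG-style TSV; validates per-sample per-chromosome non-overlap."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    _require_columns(df, [c for c in _SEG_COLS if c != "Num_Probes"], path)
    segs: list[CopyNumberSegment] = []
    for i, row in df.iterrows():
        try:
            segs.append(
                CopyNumberSegment(
                    sample_id=str(row["Sample"]),
                    chromosome=str(row["Chromosome"]),
                    start=int(row["Start"]),
                    end=int(row["End"]),
                    seg_value=float(row["Segment_Mean"]),
                    n_probes=_opt(row.get("Num_Probes"), lambda v: int(float(v))),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: line {i + 2}: {exc}") from exc
    segs.sort(key=lambda s: (s.sample_id, s.chromosome, s.start))
    offenders = []
    for j in range(1, len(segs)):
        a, b = segs[j - 1], segs[j]
        if (a.sample_id, a.chromosome) == (b.sample_id, b.chromosome) and b.start <= a.end:
            offenders.append((a, b))
    if offenders:
        desc = "; ".join(
            f"{a.sample_id}:{a.chromosome}:{a.start}-{a.end} overlaps "
            f"{b.start}-{b.end}" for a, b in offenders
        )
        raise FormatError(f"{path}: overlapping segments: {desc}")
    return segs


def write_seg(segments: Sequence[CopyNumberSegment], path) -> None:
    rows = [
        {
            "Sample": s.sample_id,
            "Chromosome": s.chromosome,
            "Start": s.start,
            "End": s.end,
            "Num_Probes": s.n_probes,
            "Segment_Mean": s.seg_value,
        }
        for s in segments
    ]
    pd.DataFrame(rows, columns=_SEG_COLS).to_csv(path, sep="\t", index=False,
                                                 lineterminator="\n")


_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False,
             "yes": True, "no": False}


def _parse_bool(value) -> bool | None:
    if value is None or value == "" or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    try:
        return _BOOL_MAP[str(value).strip().lower()]
    except KeyError:
        raise FormatError(f"unparseable boolean {value!r}") from None


_ANN_COLS = ["sample_id", "cohort", "purity", "ploidy", "wgd", "histology",
             "grade", "tamoxifen_years", "msi_flag", "bmi"]


def read_annotations(path) -> list[SampleAnnotation]:
    """Read a per-sample annotation TSV (cohort column mandatory)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    _require_columns(df, ["sample_id", "cohort"], path)
    anns: list[SampleAnnotation] = []
    for i, row in df.iterrows():
        row = row.to_dict()
        try:
            anns.append(
                SampleAnnotation(
                    sample_id=row["sample_id"],
                    cohort=row["cohort"],
                    purity=_opt(row.get("purity"), float) or 1.0,
                    ploidy=_opt(row.get("ploidy"), float),
                    wgd=_parse_bool(row.get("wgd")),
                    histology=_opt(row.get("histology"), str),
                    grade=_opt(row.get("grade"), str),
                    tamoxifen_years=_opt(row.get("tamoxifen_years"), float),
                    msi_flag=_parse_bool(row.get("msi_flag")),
                    bmi=_opt(row.get("bmi"), float),
                )
            )
        except (ValueError, FormatError) as exc:
            raise FormatError(f"{path}: line {i + 2}: {exc}") from exc
    return anns


def write_annotations(annotations: Sequence[SampleAnnotation], path) -> None:
    rows = [{c: getattr(a, c) for c in _ANN_COLS} for a in annotations]
    pd.DataFrame(rows, columns=_ANN_COLS).to_csv(path, sep="\t", index=False,
                                                 lineterminator="\n")


def read_gene_list(path, name: str | None = None) -> GeneList:
    """Read a gene list TSV with columns ``gene`` and optional ``hotspots``
    (comma-separated protein changes)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    _require_columns(df, ["gene"], path)
    hotspots = {}
    if "hotspots" in df.columns:
        for _, row in df.iterrows():
            hs = row.get("hotspots")
            if hs and not (isinstance(hs, float) and np.isnan(hs)):
                hotspots[row["gene"]] = frozenset(
                    h.strip() for h in str(hs).split(",") if h.strip()
                )
    return GeneList(name=name or path.stem, genes=tuple(df["gene"]), hotspots=hotspots)


# ---------------------------------------------------------------------------
# Filters and binarization
# ---------------------------------------------------------------------------


def filter_nonsynonymous(records: Sequence[MutationRecord]) -> list[MutationRecord]:
    """Drop noncoding/silent records (3'UTR, 5'UTR, IGR, Intron, lincRNA,
    RNA, Silent); keep everything else in input order.  Idempotent."""
    return [r for r in records if r.variant_classification not in NONCODING_CLASSES]


def binarize(
    cohort: Cohort,
    genes: GeneList,
    hotspot_only: bool = False,
    assume_filtered: bool = False,
) -> pd.DataFrame:
    """Gene-by-sample boolean mutation matrix.

    An entry is True iff the sample carries at least one qualifying
    nonsynonymous record in the gene.  With ``hotspot_only`` the record's
    protein change must additionally belong to the gene's hotspot set.
    """
    records = cohort.mutations if assume_filtered else filter_nonsynonymous(
        cohort.mutations
    )
    if hotspot_only:
        missing = [g for g in genes.genes if g not in genes.hotspots]
        if missing:
            raise ValueError(
                f"hotspot_only requested but no hotspot set for gene(s) {missing}"
            )

    def _normalize(pc: str | None) -> str | None:
        if pc is None:
            return None
        return pc[2:] if pc.startswith("p.") else pc

    samples = cohort.sample_ids
    mat = pd.DataFrame(False, index=list(genes.genes), columns=samples)
    gene_set = set(genes.genes)
    for rec in records:
        if rec.gene not in gene_set:
            continue
        if hotspot_only and _normalize(rec.protein_change) not in genes.hotspots[rec.gene]:
            continue
        mat.loc[rec.gene, rec.sample_id] = True
    return mat
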