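"""Caller-output ingestion and trio-based somatic filtering.

A patient contributes three sequencing fractions — germline PBMC DNA, the
lavage cell pellet, and lavage cell-free DNA (plus an optional tumor) — each
called independently by several somatic callers.  This module reads the
per-caller VCFs into :class:`VariantCall` records, merges callers under a
concordance rule (a variant must be reported by at least ``min_callers``
callers, default 2), restricts calls to the amplicon panel, subtracts
germline-present variants from the lavage fractions, and applies the 1%
allele-fraction reporting floor of the assay.

Coordinates: VCF records are 1-based; panel regions are 0-based half-open
(BED convention); GRCh37 throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import pysam

logger = logging.getLogger(__name__)


class Fraction(str, Enum):
    GERMLINE = "germline"
    CELL_PELLET = "cell_pellet"
    CFDNA = "cfdna"
    TUMOR = "tumor"


LAVAGE_FRACTIONS = (Fraction.CELL_PELLET, Fraction.CFDNA)


class VcfFieldError(ValueError):
    """A VCF record lacks the depth/allele-depth fields needed for AF."""


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class VariantCall:
    """One observed variant in one sample fraction, with read support."""

    patient_id: str
    fraction: Fraction
    chrom: str
    pos: int  # 1-based, GRCh37
    ref: str
    alt: str
    depth: int
    alt_reads: int
    callers: FrozenSet[str]
    gene: str = ""
    protein_change: str = ""

    def __post_init__(self):
        if not (self.chrom and self.ref and self.alt):
            raise ValueError("chrom/ref/alt must be non-empty")
        if not (0 <= self.alt_reads <= self.depth):
            raise ValueError(
                f"alt_reads {self.alt_reads} outside [0, depth={self.depth}] "
                f"at {self.chrom}:{self.pos}")

    @property
    def allele_fraction(self) -> float:
        return self.alt_reads / self.depth if self.depth > 0 else 0.0

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class PanelDefinition:
    """Targeted amplicon panel: merged regions, gene list, SNP fingerprint loci."""

    name: str
    regions: List[Tuple[str, int, int]]  # 0-based half-open
    genes: List[str]
    snp_loci: List[Tuple[str, int]] = field(default_factory=list)  # 1-based
    region_genes: Dict[Tuple[str, int, int], str] = field(default_factory=dict)

    def __post_init__(self):
        self.regions = merge_regions(self.regions)

    @property
    def amplicon_count(self) -> int:
        return len(self.regions)

    @property
    def mean_amplicon_length(self) -> int:
        if not self.regions:
            return 0
        return round(sum(e - s for _, s, e in self.regions) / len(self.regions))

    def contains(self, chrom: str, pos: int) -> bool:
        """True if 1-based ``pos`` lies in a region: (c, s, e) contains pos iff s < pos <= e."""
        for c, s, e in self.regions:
            if c == chrom and s < pos <= e:
                return True
        return False

    def gene_at(self, chrom: str, pos: int) -> str:
        for (c, s, e), g in self.region_genes.items():
            if c == chrom and s < pos <= e:
                return g
        return ""

    @classmethod
    def from_bed(cls, path, name: str = "panel",
                 snp_loci: Optional[Sequence[Tuple[str, int]]] = None) -> "PanelDefinition":
        """Read a BED file (``chrom start end [name] [gene]``, # comments allowed)."""
        regions, region_genes, genes = [], {}, []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            region = (chrom, start, end)
            regions.append(region)
            gene = parts[4] if len(parts) > 4 else (parts[3].split("_")[0] if len(parts) > 3 else "")
            if gene:
                region_genes[region] = gene
                if gene not in genes:
                    genes.append(gene)
        return cls(name=name, regions=regions, genes=genes,
                   snp_loci=list(snp_loci or []), region_genes=region_genes)


def merge_regions(regions: Iterable[Tuple[str, int, int]]) -> List[Tuple[str, int, int]]:
    """Sort and merge overlapping/adjacent half-open intervals per chromosome."""
    merged: List[Tuple[str, int, int]] = []
    for chrom, s, e in sorted(regions):
        if merged and merged[-1][0] == chrom and s <= merged[-1][2]:
            c, ps, pe = merged[-1]
            merged[-1] = (c, ps, max(pe, e))
        else:
            merged.append((chrom, s, e))
    return merged


@dataclass
class PatientTrio:
    """Germline / cell-pellet / cfDNA call sets (plus optional tumor) for one patient."""

    patient_id: str
    calls: Dict[Fraction, List[VariantCall]] = field(default_factory=dict)
    snp_genotypes: Dict[Fraction, Dict[str, Optional[str]]] = field(default_factory=dict)

    def __post_init__(self):
        for frac, calls in self.calls.items():
            for c in calls:
                if c.patient_id != self.patient_id:
                    raise ValueError(
                        f"call for {c.patient_id} in trio of {self.patient_id}")


@dataclass(frozen=True)
class ClinicalRecord:
    patient_id: str
    age: float
    race: str
    bmi: float
    diabetes: bool
    parity: int
    smoking: str
    menopausal: bool
    preop_dx: str
    final_dx: str
    cancer: bool
    stage: Optional[str] = None
    grade: Optional[str] = None

    def __post_init__(self):
        if self.age <= 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if self.cancer and not any(
                w in self.final_dx.lower() for w in ("carcinoma", "carcinosarcoma", "cancer")):
            raise ValueError(
                f"{self.patient_id}: cancer flag set but final_dx {self.final_dx!r} "
                "does not mention carcinoma/carcinosarcoma")


CLINICAL_COLUMNS = ["patient_id", "age", "race", "bmi", "diabetes", "parity",
                    "smoking", "menopausal", "preop_dx", "final_dx", "cancer",
                    "stage", "grade"]


def read_clinical_csv(path) -> pd.DataFrame:
    """Read the clinical covariate table; validates each row via ClinicalRecord."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in CLINICAL_COLUMNS[:11] if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    for rec in df.itertuples(index=False):
        ClinicalRecord(
            patient_id=str(rec.patient_id), age=float(rec.age), race=str(rec.race),
            bmi=float(rec.bmi), diabetes=bool(rec.diabetes), parity=int(rec.parity),
            smoking=str(rec.smoking), menopausal=bool(rec.menopausal),
            preop_dx=str(rec.preop_dx), final_dx=str(rec.final_dx),
            cancer=bool(rec.cancer),
            stage=getattr(rec, "stage", None), grade=getattr(rec, "grade", None))
    return df


# --------------------------------------------------------------------- VCF I/O

def read_caller_vcf(path, patient_id: str, fraction: Fraction,
                    caller: str) -> List[VariantCall]:
    """Read one per-caller, single-sample VCF into VariantCall records.

    One record is emitted per ALT allele (multi-allelic sites decomposed).
    Depth comes from FORMAT/DP (falling back to INFO/DP); allele depths from
    FORMAT/AD.  Records without usable depth information are rejected.
    """
    fraction = Fraction(fraction)
    calls: List[VariantCall] = []
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ValueError(f"malformed VCF {path}: {exc}") from exc
    with vf:
        for rec in vf.fetch() if vf.index else vf:
            if not rec.alts:
                continue
            dp, ad = _depths_for_record(rec, path)
            for i, alt in enumerate(rec.alts):
                if alt in (None, "<NON_REF>", "*"):
                    continue
                alt_reads = ad[i + 1] if ad is not None and len(ad) > i + 1 else None
                if alt_reads is None:
                    raise VcfFieldError(
                        f"{path}: no AD entry for alt {alt} at {rec.chrom}:{rec.pos}")
                calls.append(VariantCall(
                    patient_id=patient_id, fraction=fraction, chrom=rec.chrom,
                    pos=rec.pos, ref=rec.ref, alt=alt, depth=dp,
                    alt_reads=min(int(alt_reads), dp), callers=frozenset([caller])))
    return calls


def _depths_for_record(rec, path):
    dp = None
    ad = None
    if rec.samples:
        sample = rec.samples[0]
        dp = sample.get("DP")
        ad = sample.get("AD")
    if dp is None:
        try:
            dp = rec.info.get("DP")
        except ValueError:  # DP absent from the header entirely
            dp = None
    if dp is None:
        raise VcfFieldError(f"{path}: no DP field at {rec.chrom}:{rec.pos}")
    if ad is None:
        raise VcfFieldError(f"{path}: no AD field at {rec.chrom}:{rec.pos}")
    return int(dp), tuple(int(x) if x is not None else 0 for x in ad)


# ----------------------------------------------------------------- filtering

def merge_caller_outputs(calls_by_caller: Mapping[str, Sequence[VariantCall]],
                         min_callers: int = 2) -> List[VariantCall]:
    """Keep variants reported by at least ``min_callers`` callers.

    The retained record takes depth/alt_reads from the caller reporting the
    greatest depth; the caller set is the union over reporting callers.
    """
    if min_callers < 1:
        raise ConfigError(f"min_callers must be >= 1, got {min_callers}")
    by_key: Dict[Tuple, List[VariantCall]] = {}
    for caller, calls in calls_by_caller.items():
        for c in calls:
            by_key.setdefault(c.key, []).append(c)
    merged: List[VariantCall] = []
    for key in sorted(by_key):
        group = by_key[key]
        callers = frozenset().union(*(c.callers for c in group))
        if len(callers) < min_callers:
            continue
        best = max(group, key=lambda c: c.depth)
        merged.append(replace(best, callers=callers))
    return merged


def filter_by_panel(calls: Sequence[VariantCall],
                    panel: PanelDefinition) -> List[VariantCall]:
    """Retain calls inside the panel regions (half-open: s < pos <= e)."""
    panel_chroms = {c for c, _, _ in panel.regions}
    kept = []
    for c in calls:
        if c.chrom not in panel_chroms:
            logger.info("call %s:%d on chromosome absent from panel; dropped",
                        c.chrom, c.pos)
            continue
        if panel.contains(c.chrom, c.pos):
            if not c.gene:
                c = replace(c, gene=panel.gene_at(c.chrom, c.pos))
            kept.append(c)
    return kept


class MissingGermlineError(ValueError):
    pass


def subtract_germline(trio: PatientTrio,
                      snp_loci: Optional[Sequence[Tuple[str, int]]] = None
                      ) -> Dict[Fraction, List[VariantCall]]:
    """Matched-normal subtraction: drop lavage calls present in germline.

    Any variant whose (chrom, pos, ref, alt) appears in the germline call set
    is removed from the cell-pellet and cfDNA outputs, regardless of its
    germline allele fraction.  SNP fingerprint loci are identity markers and
    are never emitted as somatic.
    """
    if Fraction.GERMLINE not in trio.calls:
        raise MissingGermlineError(
            f"{trio.patient_id}: no germline fraction (tumor-only mode unsupported)")
    germline_keys = {c.key for c in trio.calls[Fraction.GERMLINE]}
    snp_set = set(map(tuple, snp_loci)) if snp_loci else set()
    out: Dict[Fraction, List[VariantCall]] = {}
    for frac in LAVAGE_FRACTIONS:
        out[frac] = [c for c in trio.calls.get(frac, [])
                     if c.key not in germline_keys
                     and (c.chrom, c.pos) not in snp_set]
    return out


def apply_reporting_threshold(calls: Sequence[VariantCall],
                              min_af: float = 0.01) -> List[VariantCall]:
    """Apply the assay's lower limit of detection (default 1%, inclusive)."""
    if not (0 < min_af <= 1):
        raise ConfigError(f"min_af must be in (0, 1], got {min_af}")
    return [c for c in calls if c.allele_fraction >= min_af]


# --------------------------------------------------------- canonical call table

CALL_COLUMNS = ["patient_id", "fraction", "chrom", "pos", "ref", "alt", "gene",
                "protein_change", "depth", "alt_reads", "allele_fraction", "callers"]


def calls_to_frame(calls: Sequence[VariantCall]) -> pd.DataFrame:
    rows = [{
        "patient_id": c.patient_id, "fraction": c.fraction.value, "chrom": c.chrom,
        "pos": c.pos, "ref": c.ref, "alt": c.alt, "gene": c.gene,
        "protein_change": c.protein_change, "depth": c.depth,
        "alt_reads": c.alt_reads, "allele_fraction": c.allele_fraction,
        "callers": ",".join(sorted(c.callers)),
    } for c in calls]
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def frame_to_calls(df: pd.DataFrame) -> List[VariantCall]:
    return [VariantCall(
        patient_id=str(r.patient_id), fraction=Fraction(r.fraction), chrom=str(r.chrom),
        pos=int(r.pos), ref=str(r.ref), alt=str(r.alt), gene=str(r.gene or ""),
        protein_change=str(r.protein_change or ""), depth=int(r.depth),
        alt_reads=int(r.alt_reads), callers=frozenset(str(r.callers).split(",")))
        for r in df.fillna({"gene": "", "protein_change": ""}).itertuples(index=False)]


def write_call_table(calls: Sequence[VariantCall], path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def read_call_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"patient_id": str, "chrom": str})
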