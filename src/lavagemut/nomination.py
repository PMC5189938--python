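"""Three-way driver / potential-driver / passenger nomination.

The rules, applied per consequence-annotated mutation against the knowledge
base (hotspot registry + gene roles + functional-impact annotations):

* **driver** — the protein position lies in a registered hotspot of a major
  endometrial driver gene, OR the mutation is truncating (stop gain or
  frameshift) in a tumor-suppressor gene among the major drivers;
* **potential driver** — otherwise, a missense mutation with predicted
  functional impact (medium or high) in a major endometrial driver gene;
* **passenger** — everything else.  Silent mutations are always passengers.

Potential drivers carry exactly one provenance sub-flag: seen in other
cancers but not endometrial (``recurrent_other_cancers``), seen in
endometrial only (``endometrial_only``), or seen in neither (``novel``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import yaml

from .consequence import (ConsequenceClass, ProteinChange, classify_consequence,
                          is_truncating, parse_protein_change)


class Label(str, Enum):
    DRIVER = "driver"
    POTENTIAL_DRIVER = "potential_driver"
    PASSENGER = "passenger"


class Role(str, Enum):
    ONCOGENE = "oncogene"
    TUMOR_SUPPRESSOR = "tumor_suppressor"
    OTHER = "other"


IMPACT_ORDER = {"neutral": 0, "low": 1, "medium": 2, "high": 3}


class NominationError(KeyError):
    pass


@dataclass(frozen=True)
class Hotspot:
    label: str
    positions: FrozenSet[int]
    changes: Tuple[str, ...]
    recurrence_endometrial: int
    recurrence_pancancer: int
    novel: bool = False

    def __post_init__(self):
        if self.recurrence_endometrial + self.recurrence_pancancer < 1:
            raise ValueError(f"hotspot {self.label}: zero total recurrence")


@dataclass
class GeneEntry:
    symbol: str
    role: Role
    major_ec_driver: bool
    on_12_gene_panel: bool
    tcga_hotspot_count: int
    tcga_mutation_count: int
    hotspots: List[Hotspot] = field(default_factory=list)


@dataclass(frozen=True)
class Annotation:
    impact: str  # neutral/low/medium/high
    seen_in_endometrial: bool
    seen_in_other_cancers: bool


class KnowledgeBase:
    """Gene roles, hotspot registry and per-mutation functional annotations."""

    def __init__(self, genes: Dict[str, GeneEntry],
                 annotations: Dict[Tuple[str, str], Annotation],
                 functional_cutoff: str = "medium"):
        self.genes = genes
        self.annotations = annotations
        if functional_cutoff not in IMPACT_ORDER:
            raise ValueError(f"unknown impact level {functional_cutoff!r}")
        self.functional_cutoff = functional_cutoff

    @classmethod
    def from_yaml(cls, path, functional_cutoff: str = "medium") -> "KnowledgeBase":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        genes: Dict[str, GeneEntry] = {}
        for symbol, g in raw["genes"].items():
            hotspots = [Hotspot(
                label=h["label"], positions=frozenset(h["positions"]),
                changes=tuple(h.get("changes", ())),
                recurrence_endometrial=h["recurrence_endometrial"],
                recurrence_pancancer=h["recurrence_pancancer"],
                novel=h.get("novel", False)) for h in g.get("hotspots", [])]
            genes[symbol] = GeneEntry(
                symbol=symbol, role=Role(g["role"]),
                major_ec_driver=g.get("major_ec_driver", False),
                on_12_gene_panel=g.get("on_12_gene_panel", False),
                tcga_hotspot_count=g.get("tcga_hotspot_count", 0),
                tcga_mutation_count=g.get("tcga_mutation_count", 0),
                hotspots=hotspots)
        annotations = {
            (a["gene"], a["protein_change"]): Annotation(
                impact=a["impact"],
                seen_in_endometrial=bool(a["seen_in_endometrial"]),
                seen_in_other_cancers=bool(a["seen_in_other_cancers"]))
            for a in raw.get("annotations", [])}
        return cls(genes, annotations, functional_cutoff=functional_cutoff)

    def gene(self, symbol: str) -> GeneEntry:
        try:
            return self.genes[symbol]
        except KeyError:
            raise NominationError(f"gene {symbol!r} absent from knowledge base")

    def impact(self, gene: str, protein_change: str) -> Optional[Annotation]:
        return self.annotations.get((gene, protein_change))

    def hotspot_match(self, gene: str, change: ProteinChange) -> Optional[Hotspot]:
        """Match at the protein-position level (any substitution at a hotspot
        position matches); among same-position entries, an exact protein-change
        match wins."""
        entry = self.gene(gene)
        positional = [h for h in entry.hotspots
                      if any(p in h.positions for p in change.positions)]
        if not positional:
            return None
        for h in positional:
            if change.raw in h.changes:
                return h
        return positional[0]


def default_knowledge_base(functional_cutoff: str = "medium") -> KnowledgeBase:
    from . import datafiles
    from importlib import resources
    with resources.as_file(datafiles.default_kb_path()) as p:
        return KnowledgeBase.from_yaml(p, functional_cutoff=functional_cutoff)


@dataclass(frozen=True)
class NominatedMutation:
    patient_id: str
    gene: str
    protein_change: str
    consequence: ConsequenceClass
    label: Label
    evidence: FrozenSet[str]
    fractions: FrozenSet[str] = frozenset()
    max_allele_fraction: float = float("nan")

    def __post_init__(self):
        if self.label is Label.DRIVER and not (
                "hotspot" in self.evidence or "truncating_tsg" in self.evidence):
            raise ValueError("driver without driver evidence flag")
        if self.label is Label.POTENTIAL_DRIVER and "functional_missense" not in self.evidence:
            raise ValueError("potential driver without functional_missense flag")


def nominate(patient_id: str, gene: str, protein_change: str, kb: KnowledgeBase,
             fractions: Iterable[str] = (), max_allele_fraction: float = float("nan"),
             ) -> NominatedMutation:
    """Nominate one mutation. Driver evidence takes precedence over the
    potential-driver rule when both would fire."""
    entry = kb.gene(gene)
    change = parse_protein_change(protein_change)
    cls = classify_consequence(change)
    evidence = set()
    label = Label.PASSENGER

    if cls is not ConsequenceClass.SILENT:
        hotspot = kb.hotspot_match(gene, change) if entry.major_ec_driver else None
        if hotspot is not None:
            evidence.add("hotspot")
        if (is_truncating(cls) and entry.role is Role.TUMOR_SUPPRESSOR
                and entry.major_ec_driver):
            evidence.add("truncating_tsg")
        if evidence:
            label = Label.DRIVER
        elif cls is ConsequenceClass.MISSENSE and entry.major_ec_driver:
            anno = kb.impact(gene, protein_change)
            if anno is not None and IMPACT_ORDER[anno.impact] >= IMPACT_ORDER[kb.functional_cutoff]:
                evidence.add("functional_missense")
                evidence.add(_provenance_flag(anno))
                label = Label.POTENTIAL_DRIVER

    return NominatedMutation(
        patient_id=patient_id, gene=gene, protein_change=protein_change,
        consequence=cls, label=label, evidence=frozenset(evidence),
        fractions=frozenset(fractions), max_allele_fraction=max_allele_fraction)


def _provenance_flag(anno: Annotation) -> str:
    if anno.seen_in_other_cancers and not anno.seen_in_endometrial:
        return "recurrent_other_cancers"
    if anno.seen_in_endometrial and not anno.seen_in_other_cancers:
        return "endometrial_only"
    if anno.seen_in_endometrial and anno.seen_in_other_cancers:
        return "recurrent_other_cancers"  # recurrent everywhere: not novel
    return "novel"


def nominate_frame(df: pd.DataFrame, kb: KnowledgeBase) -> List[NominatedMutation]:
    """Nominate every row of a call/catalogue table with gene and protein_change
    columns; fractions and allele fractions are aggregated per unique
    (patient, gene, protein_change) mutation."""
    grouped: Dict[Tuple[str, str, str], dict] = {}
    for r in df.itertuples(index=False):
        key = (str(getattr(r, "patient_id", "")), str(r.gene), str(r.protein_change))
        g = grouped.setdefault(key, {"fractions": set(), "max_af": float("nan")})
        if hasattr(r, "fraction"):
            g["fractions"].add(str(r.fraction))
        if hasattr(r, "allele_fraction"):
            af = float(r.allele_fraction)
            if not (g["max_af"] == g["max_af"]) or af > g["max_af"]:  # NaN-safe max
                g["max_af"] = af
    return [nominate(pid, gene, change, kb, fractions=g["fractions"],
                     max_allele_fraction=g["max_af"])
            for (pid, gene, change), g in grouped.items()]


def nominations_to_frame(mutations: Sequence[NominatedMutation]) -> pd.DataFrame:
    return pd.DataFrame([{
        "patient_id": m.patient_id, "gene": m.gene, "protein_change": m.protein_change,
        "consequence": m.consequence.value, "label": m.label.value,
        "evidence": ",".join(sorted(m.evidence)),
        "fractions": ",".join(sorted(m.fractions)),
        "max_allele_fraction": m.max_allele_fraction,
    } for m in mutations])


def subannotate_potential_drivers(mutations: Sequence[NominatedMutation]) -> Dict[str, int]:
    """Partition potential drivers by provenance; counts sum to their total."""
    counts = {"recurrent_other_cancers": 0, "endometrial_only": 0, "novel": 0}
    for m in mutations:
        if m.label is Label.POTENTIAL_DRIVER:
            for flag in counts:
                if flag in m.evidence:
                    counts[flag] += 1
                    break
    return counts


def label_counts(mutations: Sequence[NominatedMutation]) -> Dict[str, int]:
    out = {l.value: 0 for l in Label}
    for m in mutations:
        out[m.label.value] += 1
    return out


def rank_patients(mutations: Sequence[NominatedMutation]
                  ) -> List[Tuple[str, int, int]]:
    """Order patients by driver + potential-driver burden (descending).

    Ties break by driver count (descending) then patient_id; patients whose
    counts are all zero keep their input order via the stable sort.
    """
    per: Dict[str, List[int]] = {}
    order: Dict[str, int] = {}
    for m in mutations:
        if m.patient_id not in per:
            per[m.patient_id] = [0, 0]
            order[m.patient_id] = len(order)
        if m.label is Label.DRIVER:
            per[m.patient_id][0] += 1
        elif m.label is Label.POTENTIAL_DRIVER:
            per[m.patient_id][1] += 1
    rows = [(pid, d, p) for pid, (d, p) in per.items()]
    rows.sort(key=lambda t: (-(t[1] + t[2]), -t[1], t[0] if (t[1] + t[2]) else "",
                             order[t[0]]))
    return rows


# --------------------------------------------------------- hotspot comparison

def build_tcga_comparison(mutations: Sequence[NominatedMutation],
                          kb: KnowledgeBase) -> pd.DataFrame:
    """Per-gene comparison of lavage hotspot-mutation counts with the TCGA
    registry statistics stored in the knowledge base.

    One row per gene with at least one hotspot-evidence driver; the gene-level
    lavage count equals the sum of its per-hotspot lavage counts.  Per-hotspot
    entries are formatted ``label (lavage/tcga)``, novel entries flagged ``*``.
    """
    per_gene: Dict[str, Dict[str, int]] = {}
    for m in mutations:
        if m.label is not Label.DRIVER or "hotspot" not in m.evidence:
            continue
        hotspot = kb.hotspot_match(m.gene, parse_protein_change(m.protein_change))
        if hotspot is None:
            continue
        per_gene.setdefault(m.gene, {}).setdefault(hotspot.label, 0)
        per_gene[m.gene][hotspot.label] += 1
    rows = []
    for gene, counts in per_gene.items():
        entry = kb.gene(gene)
        details = []
        for h in entry.hotspots:
            if h.label in counts:
                flag = "*" if h.novel else ""
                details.append(f"{h.label}{flag} ({counts[h.label]}/{h.recurrence_endometrial})")
        rows.append({
            "gene": gene,
            "lavage_hotspot_mutations": sum(counts.values()),
            "tcga_hotspot_count": entry.tcga_hotspot_count,
            "tcga_mutation_count": entry.tcga_mutation_count,
            "per_hotspot": "; ".join(details),
        })
    return (pd.DataFrame(rows, columns=["gene", "lavage_hotspot_mutations",
                                        "tcga_hotspot_count", "tcga_mutation_count",
                                        "per_hotspot"])
            .sort_values("lavage_hotspot_mutations", ascending=False)
            .reset_index(drop=True))


_LABEL_RANK = {Label.DRIVER: 3, Label.POTENTIAL_DRIVER: 2, Label.PASSENGER: 1}


def mutation_matrix(mutations: Sequence[NominatedMutation],
                    genes: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Patient x gene matrix of the most consequential label per cell
    (driver > potential driver > passenger), for oncoprint-style display."""
    best: Dict[Tuple[str, str], Label] = {}
    for m in mutations:
        key = (m.patient_id, m.gene)
        if key not in best or _LABEL_RANK[m.label] > _LABEL_RANK[best[key]]:
            best[key] = m.label
    patients = sorted({p for p, _ in best})
    genes = list(genes) if genes is not None else sorted({g for _, g in best})
    mat = pd.DataFrame("", index=patients, columns=genes)
    for (p, g), label in best.items():
        if g in mat.columns:
            mat.loc[p, g] = label.value
    return mat
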