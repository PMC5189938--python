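"""Orthogonal-validation planning and assessment.

About 30% of reported mutations are selected for confirmation by an
independent technology, stratified across the allele-fraction bins so the
low-AF calls are represented.  Method assignment is a pure function of the
NGS allele fraction: Sanger sequencing at AF >= 10%, droplet digital PCR
below.  Every ddPCR entry triggers a reflex test of the same variant in the
paired lavage fraction, even when NGS reported nothing there; reflex
detections below the 1% reporting floor are recorded as sub-threshold
confirmations.  A spiked-control artifact screen partitions control-replicate
calls into truth-set matches and novel (artifact) calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cohort import DEFAULT_BINS, BIN_NAMES, bin_label

SANGER_MIN_AF = 0.10
NGS_REPORTING_AF = 0.01


class Method(str, Enum):
    SANGER = "sanger"
    DDPCR = "ddpcr"


def assign_method(af: float) -> Method:
    """Sanger at AF >= 10% (inclusive), ddPCR below."""
    return Method.SANGER if af >= SANGER_MIN_AF else Method.DDPCR


@dataclass(frozen=True)
class PlanEntry:
    variant_key: Tuple[str, str, str]  # (patient_id, gene, protein_change)
    fraction: str
    nominal_af: float
    method: Method
    reflex: bool = False


@dataclass
class ValidationPlan:
    entries: List[PlanEntry]
    selection_fraction: float
    seed: int


@dataclass
class ValidationResult:
    variant_key: Tuple[str, str, str]
    fraction: str
    method: Method
    measured_af: Optional[float]  # None = not detected
    nominal_af: float = float("nan")
    reflex: bool = False

    @property
    def detected(self) -> bool:
        return self.measured_af is not None

    @property
    def sub_threshold(self) -> bool:
        return self.detected and self.measured_af < NGS_REPORTING_AF


def select_validation_set(mutations: pd.DataFrame, selection_fraction: float = 0.30,
                          seed: int = 0,
                          bins: Sequence[Tuple[float, float]] = DEFAULT_BINS
                          ) -> ValidationPlan:
    """Stratified random selection of mutations for orthogonal validation.

    Strata are the AF bins; allocation is proportional to stratum size with
    largest-remainder rounding, so the plan size is ``selection_fraction``
    of the input within rounding.  Deterministic given the seed.
    """
    if not (0 < selection_fraction <= 1):
        raise ValueError(f"selection_fraction must be in (0, 1], got {selection_fraction}")
    if mutations.empty:
        return ValidationPlan([], selection_fraction, seed)
    rng = np.random.default_rng(seed)
    df = mutations.reset_index(drop=True)
    strata: Dict[str, List[int]] = {b: [] for b in BIN_NAMES}
    for i, af in enumerate(df["allele_fraction"]):
        strata[bin_label(af, bins)].append(i)
    total = len(df)
    target = selection_fraction * total
    quotas = {b: selection_fraction * len(ix) for b, ix in strata.items()}
    alloc = {b: int(q) for b, q in quotas.items()}
    shortfall = round(target) - sum(alloc.values())
    for b in sorted(quotas, key=lambda b: quotas[b] - alloc[b], reverse=True)[:max(shortfall, 0)]:
        if alloc[b] < len(strata[b]):
            alloc[b] += 1
    entries = []
    for b, ix in strata.items():
        chosen = rng.choice(ix, size=min(alloc[b], len(ix)), replace=False) if ix else []
        for i in sorted(int(j) for j in np.atleast_1d(chosen)):
            row = df.iloc[i]
            af = float(row["allele_fraction"])
            entries.append(PlanEntry(
                variant_key=(str(row["patient_id"]), str(row["gene"]),
                             str(row["protein_change"])),
                fraction=str(row["fraction"]), nominal_af=af,
                method=assign_method(af)))
    return ValidationPlan(entries, selection_fraction, seed)


def reflex_pair_test(entry: PlanEntry,
                     paired_mutations: Optional[pd.DataFrame] = None) -> List[PlanEntry]:
    """For a ddPCR entry, emit a reflex test of the same variant in the other
    lavage fraction (even if NGS reported nothing there). Sanger entries
    produce no reflex."""
    if entry.method is not Method.DDPCR:
        return []
    other = "cfdna" if entry.fraction == "cell_pellet" else "cell_pellet"
    nominal = float("nan")
    if paired_mutations is not None:
        pid, gene, change = entry.variant_key
        hit = paired_mutations[
            (paired_mutations["patient_id"].astype(str) == pid)
            & (paired_mutations["gene"] == gene)
            & (paired_mutations["protein_change"] == change)
            & (paired_mutations["fraction"] == other)]
        if not hit.empty:
            nominal = float(hit["allele_fraction"].iloc[0])
    return [PlanEntry(entry.variant_key, other, nominal, Method.DDPCR, reflex=True)]


@dataclass
class ConcordanceSummary:
    n_results: int
    n_validated: int
    n_sub_threshold: int
    discordant: List[ValidationResult] = field(default_factory=list)
    af_deltas: List[float] = field(default_factory=list)


def assess_concordance(results: Sequence[ValidationResult]) -> ConcordanceSummary:
    """Summarize orthogonal-assay outcomes: validated detections, reflex
    sub-threshold confirmations, discordant (undetected) entries, and
    NGS-vs-orthogonal AF deltas where both are available."""
    validated = sub = 0
    discordant: List[ValidationResult] = []
    deltas: List[float] = []
    for r in results:
        if not r.detected:
            discordant.append(r)
            continue
        if r.sub_threshold:
            sub += 1
        else:
            validated += 1
        if r.nominal_af == r.nominal_af and r.measured_af is not None:  # non-NaN nominal
            deltas.append(r.measured_af - r.nominal_af)
    return ConcordanceSummary(n_results=len(results), n_validated=validated,
                              n_sub_threshold=sub, discordant=discordant,
                              af_deltas=deltas)


@dataclass
class ArtifactScreenResult:
    recovered: List[Tuple[Tuple[str, int, str, str], float, float]]  # key, expected, observed AF
    missed: List[Tuple[str, int, str, str]]
    novel: List[Tuple[str, int, str, str]]
    deviant: List[Tuple[Tuple[str, int, str, str], float, float]] = field(default_factory=list)

    @property
    def novel_count(self) -> int:
        return len(self.novel)

    @property
    def recovery_rate(self) -> float:
        n_truth = len(self.recovered) + len(self.missed)
        return len(self.recovered) / n_truth if n_truth else float("nan")


def artifact_screen(control_calls: pd.DataFrame,
                    truth_set: Mapping[Tuple[str, int, str, str], float],
                    rel_tol: float = 0.20) -> ArtifactScreenResult:
    """Screen a control replicate's calls against the known truth set.

    Calls matching a truth variant (by chrom, pos, ref, alt) count as
    recovered when the observed AF is within ``rel_tol`` relative deviation
    of the expected AF (still recovered, but reported with their deviation,
    otherwise); any other call is novel — the pass criterion for a clean
    replicate is a novel count of zero.
    """
    recovered, novel = [], []
    seen = set()
    for r in control_calls.itertuples(index=False):
        key = (str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
        if key in truth_set:
            recovered.append((key, truth_set[key], float(r.allele_fraction)))
            seen.add(key)
        else:
            novel.append(key)
    missed = [k for k in truth_set if k not in seen]
    result = ArtifactScreenResult(recovered=recovered, missed=missed, novel=novel)
    # flag large AF deviations (informational; exact matches are never novel)
    result.deviant = [(k, e, o) for k, e, o in recovered
                      if e > 0 and abs(o - e) / e > rel_tol]
    return result
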