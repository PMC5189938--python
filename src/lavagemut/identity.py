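"""Sample-identity verification from the germline SNP spike-in panel.

The amplicon panel carries a low-concentration spike-in of high minor-allele-
fraction autosomal SNPs sequenced to ~200X, enough to genotype each fraction
independently and confirm that germline, cell pellet and cfDNA all come from
the same patient (a mislabelled or swapped tube shows up as a pairwise
genotype concordance near the random-agreement expectation instead of ~1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations
from typing import Dict, Mapping, Optional, Tuple

from .variant_io import Fraction

Genotype = str  # "0/0", "0/1", "1/1"


class Verdict(str, Enum):
    MATCH = "match"
    MISMATCH = "mismatch"
    INSUFFICIENT = "insufficient"


@dataclass
class IdentityReport:
    patient_id: str
    pairwise_concordance: Dict[Tuple[Fraction, Fraction], float] = field(default_factory=dict)
    callable_snps: Dict[Tuple[Fraction, Fraction], int] = field(default_factory=dict)
    verdict: Verdict = Verdict.INSUFFICIENT


def genotype_snp_loci(observations: Mapping[str, Tuple[int, int]],
                      min_depth: int = 50,
                      het_low: float = 0.10,
                      het_high: float = 0.90) -> Dict[str, Optional[Genotype]]:
    """Assign hard genotypes at fingerprint loci from (depth, alt_reads) pairs.

    AF < ``het_low`` -> 0/0; ``het_low``..``het_high`` -> 0/1; > ``het_high``
    -> 1/1.  Loci below ``min_depth`` are left missing (None).  The cut points
    are generous because at ~200X the three genotype AF clouds (0, 0.5, 1) are
    separated by many binomial standard deviations.
    """
    out: Dict[str, Optional[Genotype]] = {}
    for locus, (depth, alt_reads) in observations.items():
        if depth < min_depth:
            out[locus] = None
            continue
        af = alt_reads / depth if depth else 0.0
        if af < het_low:
            out[locus] = "0/0"
        elif af <= het_high:
            out[locus] = "0/1"
        else:
            out[locus] = "1/1"
    return out


def pair_concordance(a: Mapping[str, Optional[Genotype]],
                     b: Mapping[str, Optional[Genotype]]) -> Tuple[float, int]:
    """(fraction of matching genotypes among jointly callable loci, n callable)."""
    shared = [l for l in a if l in b and a[l] is not None and b[l] is not None]
    if not shared:
        return float("nan"), 0
    n_match = sum(a[l] == b[l] for l in shared)
    return n_match / len(shared), len(shared)


def trio_concordance(genotypes: Mapping[Fraction, Mapping[str, Optional[Genotype]]],
                     patient_id: str = "",
                     min_callable: int = 10,
                     match_threshold: float = 0.90) -> IdentityReport:
    """Pairwise genotype concordance across fractions and a trio verdict.

    verdict = match iff every pair has >= ``min_callable`` jointly callable
    loci and concordance >= ``match_threshold``; insufficient if any pair
    lacks callable loci; mismatch otherwise.
    """
    report = IdentityReport(patient_id=patient_id)
    fracs = sorted(genotypes, key=lambda f: f.value)
    any_insufficient = False
    any_mismatch = False
    for fa, fb in combinations(fracs, 2):
        conc, n = pair_concordance(genotypes[fa], genotypes[fb])
        report.pairwise_concordance[(fa, fb)] = conc
        report.callable_snps[(fa, fb)] = n
        if n < min_callable:
            any_insufficient = True
        elif conc < match_threshold:
            any_mismatch = True
    if any_insufficient or not report.pairwise_concordance:
        report.verdict = Verdict.INSUFFICIENT
    elif any_mismatch:
        report.verdict = Verdict.MISMATCH
    else:
        report.verdict = Verdict.MATCH
    return report
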