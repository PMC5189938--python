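"""Cohort-level statistics: AF binning, pellet/cfDNA concordance, cancer
enrichment by allele-fraction bin, and univariate clinical association scans.

Mutations are binned by allele fraction into (0, 5%], (5%, 10%] and
(10%, 100%] — matching the report labels "<=5.00%", "5.01%-10.00%",
">=10.01%" — separately for the cell-pellet and cfDNA fractions.  Per-gene
bin counts, the Pearson correlation of per-gene totals between fractions,
and the cancer-patient fraction per bin summarize concordance and the
enrichment of cancer diagnoses at high allele fractions.  Clinical
covariates are scanned univariately: ordered covariates by a one-tailed
Mann-Whitney-Wilcoxon test (mutated group stochastically larger), nominal
covariates by a Fisher exact test, with Benjamini-Hochberg adjustment across
the covariate family and a one-sided bootstrap confidence bound on the
location difference.

The module also exposes a small model/results pair, ``CohortAnalysis`` and
``CohortResults``, that runs the whole battery in one call and renders a
text summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_BINS: Tuple[Tuple[float, float], ...] = ((0.0, 0.05), (0.05, 0.10), (0.10, 1.0))
BIN_NAMES = ("low", "mid", "high")
FRACTIONS = ("cell_pellet", "cfdna")


class DataError(ValueError):
    pass


def bin_label(af: float, bins: Sequence[Tuple[float, float]] = DEFAULT_BINS) -> str:
    """Bin an allele fraction; intervals are left-open/right-closed, so 0.05
    falls in the first bin and 0.10 in the second."""
    if not (0 < af <= 1):
        raise DataError(f"allele fraction {af} outside (0, 1]")
    for name, (lo, hi) in zip(BIN_NAMES, bins):
        if lo < af <= hi:
            return name
    raise DataError(f"allele fraction {af} not covered by bins {bins}")


@dataclass
class AFBinnedTable:
    """Per gene x fraction x AF-bin mutation counts with per-gene totals."""

    counts: pd.DataFrame  # index gene, columns MultiIndex (fraction, bin)
    bins: Tuple[Tuple[float, float], ...] = DEFAULT_BINS

    def gene_sums(self, fraction: str) -> pd.Series:
        return self.counts[fraction].sum(axis=1)

    def to_table(self) -> pd.DataFrame:
        out = self.counts.copy()
        for frac in FRACTIONS:
            out[(frac, "sum")] = self.counts[frac].sum(axis=1)
        return out.sort_index(axis=1)


def bin_by_allele_fraction(mutations: pd.DataFrame,
                           bins: Sequence[Tuple[float, float]] = DEFAULT_BINS
                           ) -> AFBinnedTable:
    """Count mutations per gene, fraction and AF bin.

    ``mutations`` needs columns gene, fraction, allele_fraction; one row per
    observed mutation-in-fraction.
    """
    df = mutations.copy()
    df["bin"] = [bin_label(af, bins) for af in df["allele_fraction"]]
    genes = sorted(df["gene"].unique())
    cols = pd.MultiIndex.from_product([FRACTIONS, BIN_NAMES])
    counts = pd.DataFrame(0, index=genes, columns=cols)
    for (gene, frac, b), n in df.groupby(["gene", "fraction", "bin"]).size().items():
        if frac in FRACTIONS:
            counts.loc[gene, (frac, b)] = n
    return AFBinnedTable(counts=counts, bins=tuple(bins))


def gene_sum_correlation(table_or_x, y=None) -> Tuple[float, float]:
    """Pearson correlation of per-gene mutation totals, cell pellet vs cfDNA.

    Accepts either an :class:`AFBinnedTable` or two aligned count vectors.
    Returns (r, r_squared); zero variance in either vector is flagged as NaN.
    """
    if y is None:
        table: AFBinnedTable = table_or_x
        x = table.gene_sums("cell_pellet").to_numpy(dtype=float)
        yv = table.gene_sums("cfdna").to_numpy(dtype=float)
    else:
        x = np.asarray(table_or_x, dtype=float)
        yv = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise DataError("need at least 3 genes with totals")
    if np.std(x) == 0 or np.std(yv) == 0:
        return float("nan"), float("nan")
    r, _ = stats.pearsonr(x, yv)
    return float(r), float(r * r)


def cancer_fraction_by_bin(mutations: pd.DataFrame, clinical: pd.DataFrame,
                           bins: Sequence[Tuple[float, float]] = DEFAULT_BINS
                           ) -> pd.DataFrame:
    """Cancer-diagnosed / total patient counts per fraction x AF bin.

    A patient belongs to a bin for a fraction if she has at least one mutation
    in that bin in that fraction; a patient can appear in several bins.
    Percentages are integer-rounded; empty bins report NA.
    """
    cancer = dict(zip(clinical["patient_id"].astype(str), clinical["cancer"].astype(bool)))
    df = mutations.copy()
    df["bin"] = [bin_label(af, bins) for af in df["allele_fraction"]]
    rows = []
    for frac in FRACTIONS:
        sub = df[df["fraction"] == frac]
        for b in BIN_NAMES:
            patients = set(sub.loc[sub["bin"] == b, "patient_id"].astype(str))
            n_total = len(patients)
            n_cancer = sum(cancer.get(p, False) for p in patients)
            pct = round(100 * n_cancer / n_total) if n_total else pd.NA
            rows.append({"fraction": frac, "bin": b, "cancer_patients": n_cancer,
                         "total_patients": n_total, "percent": pct})
    return pd.DataFrame(rows)


def summarize_bin_patients(counts: pd.DataFrame) -> pd.DataFrame:
    """Bottom-row style summary from precomputed patient counts
    (columns fraction, bin, cancer_patients, total_patients)."""
    out = counts.copy()
    out["percent"] = [
        round(100 * c / t) if t else pd.NA
        for c, t in zip(out["cancer_patients"], out["total_patients"])]
    return out


# ------------------------------------------------------------------ inference

def fisher_exact_2x2(table, alternative: str = "two_sided") -> float:
    """Fisher exact p for a 2x2 table; two-sided sums all tables with
    probability <= the observed one."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}[alternative]
    return float(stats.fisher_exact(t, alternative=alt)[1])


def fisher_exact_rxc(table, n_mc: int = 20000,
                     rng: Optional[np.random.Generator] = None) -> float:
    """Conditional exact test for an r x c contingency table, estimated by
    Monte Carlo: sample tables with the observed margins and count those
    whose conditional (multivariate hypergeometric) probability does not
    exceed the observed table's. 2x2 input falls through to the exact test."""
    t = np.asarray(table, dtype=int)
    if t.shape == (2, 2):
        return fisher_exact_2x2(t)
    rng = rng or np.random.default_rng(0)
    row_labels = np.repeat(np.arange(t.shape[0]), t.sum(axis=1))
    col_labels = np.repeat(np.arange(t.shape[1]), t.sum(axis=0))

    def log_prob(tab):
        # conditional probability up to a margin-only constant
        return -sum(math.lgamma(x + 1) for x in tab.ravel())

    obs = log_prob(t)
    hits = 0
    for _ in range(n_mc):
        perm = rng.permutation(col_labels)
        tab = np.zeros_like(t)
        np.add.at(tab, (row_labels, perm), 1)
        if log_prob(tab) <= obs + 1e-12:
            hits += 1
    return (hits + 1) / (n_mc + 1)


def mann_whitney_one_tailed(group_a: Sequence[float], group_b: Sequence[float]
                            ) -> Tuple[float, float]:
    """One-sided Mann-Whitney-Wilcoxon test of ``group_a`` stochastically
    larger than ``group_b``.

    Exact enumeration when both groups have n <= 20 and no ties; otherwise
    the tie-corrected normal approximation.  Returns (U, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size <= 20 and b.size <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="greater", method=method)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvalues: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def one_sided_location_ci(group_a: Sequence[float], group_b: Sequence[float],
                          level: float = 0.95, n_boot: int = 10000,
                          seed: Optional[int] = None) -> float:
    """Lower bound of the one-sided bootstrap percentile CI for the difference
    of means (a - b); the upper bound is +infinity."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need >= 2 values")
    rng = np.random.default_rng(seed)
    diffs = (a[rng.integers(0, a.size, size=(n_boot, a.size))].mean(axis=1)
             - b[rng.integers(0, b.size, size=(n_boot, b.size))].mean(axis=1))
    return float(np.quantile(diffs, 1 - level))


def bin_enrichment_test(mutations: pd.DataFrame, clinical: pd.DataFrame,
                        fraction: str,
                        bins: Sequence[Tuple[float, float]] = DEFAULT_BINS
                        ) -> Optional[float]:
    """Fisher test of cancer status x high-AF membership for one fraction.

    2x2: patients with >= 1 mutation in the >10% bin vs patients with
    mutations only in the lower bins; returns None (NA) on degenerate
    margins.  The published analysis's exact contingency construction is not
    recoverable, so this construction is a package choice.
    """
    cancer = dict(zip(clinical["patient_id"].astype(str), clinical["cancer"].astype(bool)))
    sub = mutations[mutations["fraction"] == fraction]
    if sub.empty:
        return None
    high, lower = set(), set()
    for r in sub.itertuples(index=False):
        (high if bin_label(r.allele_fraction, bins) == "high" else lower).add(
            str(r.patient_id))
    lower -= high
    if not high or not lower:
        return None
    table = [[sum(cancer.get(p, False) for p in high),
              sum(not cancer.get(p, False) for p in high)],
             [sum(cancer.get(p, False) for p in lower),
              sum(not cancer.get(p, False) for p in lower)]]
    if sum(table[0]) == 0 or sum(table[1]) == 0:
        return None
    return fisher_exact_2x2(table, alternative="two_sided")


# ------------------------------------------------------- association scanning

ORDERED_COVARIATES = ("age", "bmi", "parity", "menopausal", "smoking", "diabetes")
NOMINAL_COVARIATES = ("race",)
SMOKING_ORDER = {"never": 0, "former": 1, "current": 2}


@dataclass
class AssociationResult:
    covariate: str
    test: str
    p_raw: float
    p_adjusted: float = float("nan")
    mean_positive: float = float("nan")
    mean_negative: float = float("nan")
    ci_lower: float = float("nan")  # one-sided 95% bound; upper is +inf


def clinical_association_scan(clinical: pd.DataFrame,
                              mutation_status: Mapping[str, bool],
                              covariates: Sequence[str] = ORDERED_COVARIATES + NOMINAL_COVARIATES,
                              seed: Optional[int] = None,
                              ) -> List[AssociationResult]:
    """Univariate scan of clinical covariates against mutation status.

    ``mutation_status`` maps patient_id -> carries >= 1 driver or potential
    driver.  Ordered covariates (age, bmi, parity; menopausal and diabetes
    coded 0/1; smoking coded never<former<current) use the one-tailed
    Mann-Whitney test; nominal covariates (race) use the Fisher exact test on
    the contingency table.  BH adjustment runs across the scanned family.
    """
    df = clinical.copy()
    df["patient_id"] = df["patient_id"].astype(str)
    df["_status"] = df["patient_id"].map(lambda p: mutation_status.get(p))
    df = df[df["_status"].notna()]
    pos = df[df["_status"].astype(bool)]
    neg = df[~df["_status"].astype(bool)]
    results: List[AssociationResult] = []
    if pos.empty or neg.empty:
        return [AssociationResult(c, "NA", float("nan")) for c in covariates]

    for cov in covariates:
        if cov not in df.columns or df[cov].isna().all():
            continue
        if cov in NOMINAL_COVARIATES:
            table = pd.crosstab(df["_status"].astype(bool), df[cov]).to_numpy()
            p = fisher_exact_rxc(table, rng=np.random.default_rng(seed))
            results.append(AssociationResult(cov, "fisher_exact", p))
        else:
            a = _ordered_values(pos[cov])
            b = _ordered_values(neg[cov])
            _, p = mann_whitney_one_tailed(a, b)
            ci = one_sided_location_ci(a, b, seed=seed) if (len(a) > 1 and len(b) > 1) \
                else float("nan")
            results.append(AssociationResult(
                cov, "mann_whitney_one_tailed", p,
                mean_positive=float(np.mean(a)), mean_negative=float(np.mean(b)),
                ci_lower=ci))
    adj = bh_adjust([r.p_raw for r in results])
    for r, q in zip(results, adj):
        r.p_adjusted = q
    return results


def _ordered_values(series: pd.Series) -> np.ndarray:
    s = series.dropna()
    if s.dtype == bool:
        return s.astype(float).to_numpy()
    if s.dtype == object:
        return s.map(lambda v: SMOKING_ORDER.get(str(v).lower(), np.nan)).dropna().to_numpy()
    return s.astype(float).to_numpy()


def fraction_concordance(mutations: pd.DataFrame,
                         clinical: Optional[pd.DataFrame] = None) -> Dict[str, object]:
    """Pellet-only / cfDNA-only / both partition per unique mutation, plus
    per-gene unique-patient (and cancer-diagnosed-patient) counts."""
    cancer = {}
    if clinical is not None:
        cancer = dict(zip(clinical["patient_id"].astype(str),
                          clinical["cancer"].astype(bool)))
    seen: Dict[Tuple[str, str, str], set] = {}
    for r in mutations.itertuples(index=False):
        key = (str(r.patient_id), str(r.gene), str(r.protein_change))
        seen.setdefault(key, set()).add(str(r.fraction))
    partition = {"both": 0, "pellet_only": 0, "cfdna_only": 0}
    per_mutation = {}
    for key, fracs in seen.items():
        if {"cell_pellet", "cfdna"} <= fracs:
            cat = "both"
        elif "cell_pellet" in fracs:
            cat = "pellet_only"
        else:
            cat = "cfdna_only"
        partition[cat] += 1
        per_mutation[key] = cat
    gene_rows = []
    by_gene: Dict[str, set] = {}
    for (pid, gene, _), _fr in seen.items():
        by_gene.setdefault(gene, set()).add(pid)
    for gene, pids in sorted(by_gene.items()):
        gene_rows.append({"gene": gene, "unique_patients": len(pids),
                          "cancer_patients": sum(cancer.get(p, False) for p in pids)})
    return {"partition": partition, "per_mutation": per_mutation,
            "per_gene": pd.DataFrame(gene_rows)}


# ----------------------------------------------------------- model / results

class CohortAnalysis:
    """Cohort-level analysis model over nominated mutations and clinical data.

    Parameters
    ----------
    mutations : DataFrame with patient_id, gene, protein_change, fraction,
        allele_fraction and label columns (one row per mutation-in-fraction).
    clinical : clinical covariate table (see ``variant_io.CLINICAL_COLUMNS``).
    bins : AF bin edges, default (0,5%], (5%,10%], (10%,100%].
    """

    def __init__(self, mutations: pd.DataFrame, clinical: pd.DataFrame,
                 bins: Sequence[Tuple[float, float]] = DEFAULT_BINS):
        self.mutations = self._normalize(mutations)
        self.clinical = clinical
        self.bins = tuple(bins)

    @staticmethod
    def _normalize(mutations: pd.DataFrame) -> pd.DataFrame:
        """Accept either one row per mutation-in-fraction (fraction,
        allele_fraction columns) or the nominated-table format (comma-joined
        fractions, max_allele_fraction), exploding the latter."""
        if "fraction" in mutations.columns:
            return mutations
        df = mutations.copy()
        df["fraction"] = df["fractions"].astype(str).str.split(",")
        df = df.explode("fraction")
        df["allele_fraction"] = df["max_allele_fraction"].astype(float)
        return df.reset_index(drop=True)

    @classmethod
    def from_files(cls, nominated_tsv, clinical_csv, **kwargs) -> "CohortAnalysis":
        from .variant_io import read_clinical_csv
        mutations = pd.read_csv(nominated_tsv, sep="\t", dtype={"patient_id": str})
        return cls(mutations, read_clinical_csv(clinical_csv), **kwargs)

    def mutation_status(self) -> Dict[str, bool]:
        """patient -> carries >= 1 driver or potential-driver mutation."""
        positive = set(self.mutations.loc[
            self.mutations["label"].isin(["driver", "potential_driver"]),
            "patient_id"].astype(str))
        return {str(p): (str(p) in positive)
                for p in self.clinical["patient_id"].astype(str)}

    def fit(self, seed: Optional[int] = None) -> "CohortResults":
        table = bin_by_allele_fraction(self.mutations, self.bins)
        r, r2 = gene_sum_correlation(table)
        by_bin = cancer_fraction_by_bin(self.mutations, self.clinical, self.bins)
        enrichment = {frac: bin_enrichment_test(self.mutations, self.clinical,
                                                frac, self.bins)
                      for frac in FRACTIONS}
        scan = clinical_association_scan(self.clinical, self.mutation_status(),
                                         seed=seed)
        concordance = fraction_concordance(self.mutations, self.clinical)
        return CohortResults(model=self, af_table=table, pearson_r=r, r_squared=r2,
                             cancer_by_bin=by_bin, enrichment_p=enrichment,
                             associations=scan, concordance=concordance)


@dataclass
class CohortResults:
    model: CohortAnalysis
    af_table: AFBinnedTable
    pearson_r: float
    r_squared: float
    cancer_by_bin: pd.DataFrame
    enrichment_p: Dict[str, Optional[float]]
    associations: List[AssociationResult]
    concordance: Dict[str, object]

    def association_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "covariate": a.covariate, "test": a.test, "p_raw": a.p_raw,
            "p_bh": a.p_adjusted, "mean_positive": a.mean_positive,
            "mean_negative": a.mean_negative, "ci95_lower": a.ci_lower,
        } for a in self.associations])

    def summary(self) -> str:
        lines = ["Uterine-lavage cohort analysis", "=" * 34]
        lines.append(f"mutation rows: {len(self.model.mutations)}; "
                     f"patients: {self.model.clinical.shape[0]}")
        lines.append(f"per-gene pellet/cfDNA correlation: "
                     f"r = {self.pearson_r:.3f}, r^2 = {self.r_squared:.2f}")
        lines.append("\nCancer-diagnosed patients by AF bin:")
        lines.append(self.cancer_by_bin.to_string(index=False))
        lines.append("\nHigh-AF (>10%) enrichment, Fisher p:")
        for frac, p in self.enrichment_p.items():
            lines.append(f"  {frac}: {'NA' if p is None else format(p, '.4g')}")
        lines.append("\nClinical associations (one-tailed MWW / Fisher, BH-adjusted):")
        lines.append(self.association_frame().to_string(
            index=False, float_format=lambda v: f"{v:.4g}"))
        part = self.concordance["partition"]
        lines.append(f"\nFraction concordance: both={part['both']}, "
                     f"pellet_only={part['pellet_only']}, cfdna_only={part['cfdna_only']}")
        return "\n".join(lines)
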