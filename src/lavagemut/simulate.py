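"""Synthetic cohort, trio-VCF and control-replicate generation.

The generator emulates the statistical structure the analysis pipeline
assumes: a 107-patient cohort with a 102/107 QC pass rate, 58/102 mutated
patients and 7/107 cancer prevalence; somatic allele fractions drawn from a
log-normal truncated to (1%, 30.4%] with implied mean ~3%; ~5,000X amplicon
coverage with binomial read support; per-gene mutation burdens proportional
to the published hotspot-table counts (hence correlated between the pellet
and cfDNA fractions through the shared-mutation probability); an age shift
of +7.61 y for mutated patients with menopausal status coupled to age; and
elevated odds that a cancer patient carries a >10% AF mutation.

Every draw flows from ``SimulationConfig.seed`` through per-patient seed
sequences, so identical configs reproduce outputs byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam

from . import datafiles
from .variant_io import Fraction

CALLERS = ("mutect", "varscan", "lofreq")

# GRCh37 chromosome lengths for the contigs the panel touches
GRCH37_LENGTHS = {
    "1": 249250621, "2": 243199373, "3": 198022430, "4": 191154276,
    "5": 180915260, "6": 171115067, "7": 159138663, "8": 146364022,
    "9": 141213431, "10": 135534747, "11": 135006516, "12": 133851895,
    "13": 115169878, "14": 107349540, "15": 102531392, "16": 90354753,
    "17": 81195210, "18": 78077248, "19": 59128983, "20": 63025520,
    "21": 48129895, "22": 51304566,
}

# per-gene mutation weights proportional to the published lavage counts
GENE_WEIGHTS = {
    "PIK3CA": 33, "PTEN": 25, "KRAS": 23, "PIK3R1": 11, "FBXW7": 8,
    "CTNNB1": 6, "ARID1A": 5, "FGFR2": 4, "TP53": 2, "ATM": 2,
    "APC": 1, "RB1": 1,
}


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_patients: int = 107
    cancer_prevalence: float = 7 / 107
    qc_pass_rate: float = 102 / 107
    mutated_fraction: float = 58 / 102
    mean_depth: int = 5000
    snp_depth: int = 200
    af_log_mu: float = -4.3
    af_log_sigma: float = 1.0
    af_min: float = 0.01
    af_max: float = 0.304
    age_mean_nonmutated: float = 50.35
    age_shift: float = 7.61
    age_sd: float = 11.0
    menopause_center: float = 51.0
    menopause_scale: float = 5.0
    cancer_high_af_prob: float = 0.75
    shared_fraction_prob: float = 0.6
    caller_dropout: float = 0.05
    mutation_count_mean: float = 2.2
    mutation_count_shape: float = 1.2
    max_mutations_per_patient: int = 20
    n_germline_candidates: int = 40

    def __post_init__(self):
        for name in ("cancer_prevalence", "qc_pass_rate", "mutated_fraction",
                     "cancer_high_af_prob", "shared_fraction_prob", "caller_dropout"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0 < self.af_min < self.af_max <= 1):
            raise ValueError("need 0 < af_min < af_max <= 1")

    @property
    def implied_mean_af(self) -> float:
        """Mean of the truncated log-normal AF distribution (numeric)."""
        lo, hi = math.log(self.af_min), math.log(self.af_max)
        xs = np.linspace(lo, hi, 4001)
        pdf = np.exp(-0.5 * ((xs - self.af_log_mu) / self.af_log_sigma) ** 2)
        return float(np.trapezoid(np.exp(xs) * pdf, xs) / np.trapezoid(pdf, xs))


def _patient_rng(config: SimulationConfig, patient_index: int,
                 stream: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, patient_index, stream]))


def _truncated_lognormal_af(rng, config: SimulationConfig, size: int) -> np.ndarray:
    lo, hi = math.log(config.af_min), math.log(config.af_max)
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(config.af_log_mu, config.af_log_sigma, size=4 * (size - filled))
        draw = draw[(draw > lo) & (draw <= hi)]
        take = min(len(draw), size - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return np.exp(out)


RACES = (["white"] * 66 + ["african_american"] * 13 + ["asian"] * 11
         + ["hispanic"] * 5 + ["other"] * 5)
SMOKING = ["never"] * 80 + ["former"] * 18 + ["current"] * 2
BENIGN_DX = (["polyp"] * 56 + ["normal endometrium"] * 16 + ["fibroid"] * 12
             + ["polyp and fibroid"] * 5 + ["endometrial hyperplasia"] * 3
             + ["other"] * 2)
PREOP_DX = (["abnormal bleeding"] * 47 + ["uterine polyp"] * 28
            + ["thickened endometrium"] * 9 + ["uterine fibroid"] * 6
            + ["other"] * 10)


def _catalog_frame() -> pd.DataFrame:
    cat = datafiles.load_mutation_catalog().reset_index(drop=True)
    weights = np.array([GENE_WEIGHTS.get(g, 1) for g in cat["gene"]], dtype=float)
    per_gene = cat["gene"].map(cat["gene"].value_counts())
    cat["weight"] = weights / per_gene.to_numpy()
    return cat


def _genomic_map(catalog: pd.DataFrame) -> pd.DataFrame:
    """Deterministic, injective mapping of catalogue entries onto panel
    amplicons (synthetic coordinates for rendering and round-tripping)."""
    panel = datafiles.load_default_panel()
    by_gene_regions: Dict[str, List[Tuple[str, int, int]]] = {}
    for region, gene in panel.region_genes.items():
        by_gene_regions.setdefault(gene, []).append(region)
    for regions in by_gene_regions.values():
        regions.sort()
    rows = []
    counters: Dict[str, int] = {}
    for rec in catalog.itertuples(index=False):
        j = counters.get(rec.gene, 0)
        counters[rec.gene] = j + 1
        regions = by_gene_regions[rec.gene]
        chrom, start, end = regions[j % len(regions)]
        offset = 10 + 4 * (j // len(regions))
        pos = start + offset + 1  # 1-based, inside (start, end]
        change = str(rec.protein_change)
        if change.endswith("fs"):
            ref, alt = "CA", "C"
        elif "del" in change:
            ref, alt = "CAAA", "C"
        else:
            ref, alt = "C", "T"
        rows.append({"gene": rec.gene, "protein_change": change,
                     "chrom": chrom, "pos": pos, "ref": ref, "alt": alt})
    return pd.DataFrame(rows)


def catalog_genomic_table() -> pd.DataFrame:
    """Catalogue entries with their panel genomic coordinates
    (chrom, pos, ref, alt, gene, protein_change) — the lookup an annotation
    step uses to attach protein changes to panel calls."""
    cat = _catalog_frame()
    return cat.merge(_genomic_map(cat), on=["gene", "protein_change"])[
        ["chrom", "pos", "ref", "alt", "gene", "protein_change"]]


class CohortSimulator:
    """Draws whole cohorts (clinical table + truth mutation list) and renders
    per-patient trio VCFs under a :class:`SimulationConfig`."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        self.catalog = _catalog_frame()
        self.gmap = _genomic_map(self.catalog)
        self.catalog = self.catalog.merge(self.gmap, on=["gene", "protein_change"])
        self.panel = datafiles.load_default_panel()
        self.snps = datafiles.load_snp_loci()
        # fixed germline candidate sites: high offsets inside amplicons,
        # disjoint from the somatic map by construction
        regions = sorted(self.panel.regions)
        self.germline_candidates = []
        for i in range(self.config.n_germline_candidates):
            chrom, s, e = regions[(i * 3) % len(regions)]
            pos = s + 100 + (i % 30)
            self.germline_candidates.append((chrom, pos + 1, "G", "A"))

    # ------------------------------------------------------------- cohort
    def simulate_cohort(self) -> Tuple[pd.DataFrame, pd.DataFrame]:
        """Returns (clinical table, truth mutation table).

        The truth table has one row per (patient, mutation) with the truth
        label from the catalogue, the drawn allele fraction and the fractions
        the mutation is planted in.
        """
        cfg = self.config
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 10_000]))
        n = cfg.n_patients
        ids = [f"PT{i + 1:03d}" for i in range(n)]
        qc_pass = np.zeros(n, dtype=bool)
        qc_pass[rng.choice(n, size=round(n * cfg.qc_pass_rate), replace=False)] = True
        mutated = np.zeros(n, dtype=bool)
        passed_idx = np.flatnonzero(qc_pass)
        n_mut = round(len(passed_idx) * cfg.mutated_fraction)
        mutated[rng.choice(passed_idx, size=n_mut, replace=False)] = True

        n_cancer = rng.binomial(n, cfg.cancer_prevalence)
        cancer = np.zeros(n, dtype=bool)
        mut_idx = np.flatnonzero(mutated)
        if n_cancer and len(mut_idx):
            cancer[rng.choice(mut_idx, size=min(n_cancer, len(mut_idx)),
                              replace=False)] = True

        truth_rows = self._draw_truth(rng, ids, mutated, cancer)
        truth = pd.DataFrame(truth_rows, columns=[
            "patient_id", "gene", "protein_change", "expected_label", "af",
            "in_pellet", "in_cfdna", "chrom", "pos", "ref", "alt"])

        # the age shift attaches to driver/potential-driver carrier status,
        # the grouping the cohort-level association analysis uses
        carriers = set(truth.loc[truth["expected_label"].isin(
            ["driver", "potential_driver"]), "patient_id"])
        carrier = np.array([pid in carriers for pid in ids])
        age = np.where(
            carrier,
            rng.normal(cfg.age_mean_nonmutated + cfg.age_shift, cfg.age_sd, n),
            rng.normal(cfg.age_mean_nonmutated, cfg.age_sd, n))
        age = np.clip(age, 22.0, None)
        menop = rng.random(n) < 1 / (1 + np.exp(-(age - cfg.menopause_center)
                                                / cfg.menopause_scale))

        clinical = pd.DataFrame({
            "patient_id": ids,
            "age": np.round(age, 1),
            "race": rng.choice(RACES, size=n),
            "bmi": np.round(np.clip(rng.normal(28, 6, n), 16, None), 1),
            "diabetes": rng.random(n) < 0.15,
            "parity": rng.choice([0, 1, 2, 3, 4, 6], size=n,
                                 p=[0.42, 0.18, 0.18, 0.12, 0.06, 0.04]),
            "smoking": rng.choice(SMOKING, size=n),
            "menopausal": menop,
            "preop_dx": rng.choice(PREOP_DX, size=n),
            "final_dx": [""] * n,
            "cancer": cancer,
            "stage": [""] * n,
            "grade": [""] * n,
            "qc_pass": qc_pass,
        })
        benign = rng.choice(BENIGN_DX, size=n)
        clinical["final_dx"] = np.where(cancer, "endometrioid adenocarcinoma", benign)
        clinical.loc[cancer, "stage"] = "IA"
        clinical.loc[cancer, "grade"] = "1"
        return clinical, truth

    def _draw_truth(self, rng, ids, mutated, cancer) -> List[dict]:
        cfg = self.config
        truth_rows = []
        drivers = self.catalog[self.catalog["expected_label"] == "driver"]
        for i in np.flatnonzero(mutated):
            prng = _patient_rng(cfg, i, stream=1)
            k = self._draw_mutation_count(prng)
            idx = prng.choice(len(self.catalog), size=k, replace=False,
                              p=self.catalog["weight"] / self.catalog["weight"].sum())
            rows = self.catalog.iloc[idx].copy()
            if cancer[i] and not (rows["expected_label"] == "driver").any():
                rows.iloc[0] = drivers.iloc[prng.integers(len(drivers))]
            afs = _truncated_lognormal_af(prng, cfg, len(rows))
            if cancer[i] and prng.random() < cfg.cancer_high_af_prob:
                afs[prng.integers(len(afs))] = prng.uniform(
                    max(0.101, cfg.af_min), cfg.af_max)
            both = prng.random(len(rows)) < cfg.shared_fraction_prob
            pellet_only = prng.random(len(rows)) < 0.5
            for j, rec in enumerate(rows.itertuples(index=False)):
                in_pellet = bool(both[j] or pellet_only[j])
                in_cfdna = bool(both[j] or not pellet_only[j])
                truth_rows.append({
                    "patient_id": ids[i], "gene": rec.gene,
                    "protein_change": rec.protein_change,
                    "expected_label": rec.expected_label,
                    "af": float(afs[j]), "in_pellet": in_pellet,
                    "in_cfdna": in_cfdna, "chrom": rec.chrom, "pos": rec.pos,
                    "ref": rec.ref, "alt": rec.alt,
                })
        return truth_rows

    def _draw_mutation_count(self, rng) -> int:
        cfg = self.config
        r = cfg.mutation_count_shape
        p = r / (r + cfg.mutation_count_mean)
        for _ in range(1000):
            k = rng.negative_binomial(r, p)
            if 1 <= k <= cfg.max_mutations_per_patient:
                return int(k)
        return 1

    # ----------------------------------------------------------- rendering
    def patient_germline(self, patient_index: int) -> List[Tuple[str, int, str, str, float]]:
        """Germline variants (with AF 0.5 het / 1.0 hom) for one patient."""
        rng = _patient_rng(self.config, patient_index, stream=2)
        out = []
        for site in self.germline_candidates:
            u = rng.random()
            if u < 0.35:
                out.append((*site, 0.5))
            elif u < 0.5:
                out.append((*site, 1.0))
        return out

    def patient_snp_genotypes(self, patient_index: int) -> Dict[str, str]:
        rng = _patient_rng(self.config, patient_index, stream=3)
        genos = {}
        for rec in self.snps.itertuples(index=False):
            maf = float(rec.maf)
            u = rng.random()
            if u < (1 - maf) ** 2:
                genos[str(rec.locus_id)] = "0/0"
            elif u < (1 - maf) ** 2 + 2 * maf * (1 - maf):
                genos[str(rec.locus_id)] = "0/1"
            else:
                genos[str(rec.locus_id)] = "1/1"
        return genos

    def render_trio_vcfs(self, patient_id: str, truth: pd.DataFrame,
                         out_dir, patient_index: Optional[int] = None,
                         swap_snp_source: Optional[int] = None
                         ) -> Dict[Tuple[str, str], Path]:
        """Write per-fraction, per-caller VCFs for one patient.

        ``truth`` is the patient's slice of the cohort truth table.  Returns
        a mapping (fraction, caller) -> path.  ``swap_snp_source`` substitutes
        another patient's SNP genotypes into the cfDNA fraction, to simulate a
        sample swap for identity-check testing.
        """
        cfg = self.config
        if patient_index is None:
            patient_index = int(patient_id.lstrip("PT")) - 1
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rng = _patient_rng(cfg, patient_index, stream=4)
        germline = self.patient_germline(patient_index)
        genos = self.patient_snp_genotypes(patient_index)
        swap_genos = (self.patient_snp_genotypes(swap_snp_source)
                      if swap_snp_source is not None else None)

        somatic = {Fraction.CELL_PELLET: [], Fraction.CFDNA: []}
        for rec in truth.itertuples(index=False):
            if rec.in_pellet:
                somatic[Fraction.CELL_PELLET].append(rec)
            if rec.in_cfdna:
                somatic[Fraction.CFDNA].append(rec)

        paths: Dict[Tuple[str, str], Path] = {}
        for fraction in (Fraction.GERMLINE, Fraction.CELL_PELLET, Fraction.CFDNA):
            records = []
            for chrom, pos, ref, alt, af in germline:
                depth = max(1, int(rng.poisson(cfg.mean_depth)))
                alt_reads = int(rng.binomial(depth, af))
                records.append((chrom, pos, ref, alt, depth, alt_reads, None))
            use_genos = genos
            if swap_genos is not None and fraction is Fraction.CFDNA:
                use_genos = swap_genos
            for snp in self.snps.itertuples(index=False):
                g = use_genos[str(snp.locus_id)]
                af = {"0/0": 0.001, "0/1": 0.5, "1/1": 0.999}[g]
                depth = max(1, int(rng.poisson(cfg.snp_depth)))
                alt_reads = int(rng.binomial(depth, af))
                records.append((str(snp.chrom), int(snp.pos), str(snp.ref),
                                str(snp.alt), depth, alt_reads, g))
            dropout_draws = {}
            if fraction is not Fraction.GERMLINE:
                for rec in somatic[fraction]:
                    depth = max(1, int(rng.poisson(cfg.mean_depth)))
                    alt_reads = int(rng.binomial(depth, rec.af))
                    drops = rng.random(len(CALLERS)) < cfg.caller_dropout
                    records.append((rec.chrom, int(rec.pos), rec.ref, rec.alt,
                                    depth, alt_reads, None))
                    dropout_draws[(rec.chrom, int(rec.pos), rec.ref, rec.alt)] = drops
            records.sort(key=lambda r: (_chrom_sort_key(r[0]), r[1]))
            for ci, caller in enumerate(CALLERS):
                path = out_dir / f"{patient_id}_{fraction.value}_{caller}.vcf"
                kept = [r for r in records
                        if not dropout_draws.get((r[0], r[1], r[2], r[3]),
                                                 (False,) * len(CALLERS))[ci]]
                _write_vcf(path, f"{patient_id}_{fraction.value}", kept)
                paths[(fraction.value, caller)] = path
        return paths

    # ------------------------------------------------------ control replicates
    def make_control_truth_set(self, n_variants: int = 20
                               ) -> Dict[Tuple[str, int, str, str], float]:
        """A reference-material truth set: germline-like variants at AF 0.5/1.0
        plus a few engineered somatic-like variants at 5%-25%."""
        rng = np.random.default_rng(np.random.SeedSequence([self.config.seed, 20_000]))
        regions = sorted(self.panel.regions)
        truth = {}
        for i in range(n_variants):
            chrom, s, e = regions[(i * 5) % len(regions)]
            pos = s + 40 + i % 20 + 1
            if i < n_variants - 5:
                af = 0.5 if i % 3 else 1.0
            else:
                af = float(rng.uniform(0.05, 0.25))
            truth[(chrom, pos, "G", "T")] = af
        return truth

    def simulate_control_replicates(self, truth_set: Mapping[Tuple[str, int, str, str], float],
                                    n_replicates: int = 4,
                                    artifact_rate: float = 0.0,
                                    min_af: float = 0.01) -> List[pd.DataFrame]:
        """Render control-replicate call tables at 12,000-26,000X.

        ``artifact_rate`` is the expected number of spurious calls per
        amplicon per replicate (0 = clean mode).
        """
        cfg = self.config
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 30_000]))
        regions = sorted(self.panel.regions)
        reps = []
        for rep in range(n_replicates):
            depth_mean = int(rng.integers(12_000, 26_001))
            rows = []
            for (chrom, pos, ref, alt), af in truth_set.items():
                depth = max(1, int(rng.poisson(depth_mean)))
                alt_reads = int(rng.binomial(depth, af))
                if alt_reads / depth >= min_af:
                    rows.append({"replicate": rep, "chrom": chrom, "pos": pos,
                                 "ref": ref, "alt": alt, "depth": depth,
                                 "alt_reads": alt_reads,
                                 "allele_fraction": alt_reads / depth})
            n_art = rng.poisson(artifact_rate * len(regions))
            for _ in range(n_art):
                chrom, s, e = regions[rng.integers(len(regions))]
                pos = int(s + rng.integers(1, e - s + 1))
                depth = max(1, int(rng.poisson(depth_mean)))
                af = float(rng.uniform(0.011, 0.05))
                alt_reads = max(int(rng.binomial(depth, af)), int(depth * min_af) + 1)
                rows.append({"replicate": rep, "chrom": chrom, "pos": pos,
                             "ref": "A", "alt": "G", "depth": depth,
                             "alt_reads": alt_reads,
                             "allele_fraction": alt_reads / depth})
            reps.append(pd.DataFrame(rows, columns=[
                "replicate", "chrom", "pos", "ref", "alt", "depth",
                "alt_reads", "allele_fraction"]))
        return reps


def _chrom_sort_key(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


def _write_vcf(path: Path, sample: str, records) -> None:
    header = pysam.VariantHeader()
    for chrom, length in GRCH37_LENGTHS.items():
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for chrom, pos, ref, alt, depth, alt_reads, gt in records:
            rec = vf.new_record(contig=chrom, start=pos - 1,
                                alleles=(ref, alt))
            s = rec.samples[sample]
            s["DP"] = depth
            s["AD"] = (depth - alt_reads, alt_reads)
            if gt is not None:
                s["GT"] = tuple(int(x) for x in gt.split("/"))
            vf.write(rec)


# ------------------------------------------------------------ recovery harness

def estimate_age_shift(clinical: pd.DataFrame, truth: pd.DataFrame
                       ) -> Tuple[float, float]:
    """(estimated mutated-vs-non-mutated age shift, one-tailed MWW p) using
    driver/potential-driver carrier status, among QC-passed patients."""
    from .cohort import mann_whitney_one_tailed
    carriers = set(truth.loc[truth["expected_label"].isin(
        ["driver", "potential_driver"]), "patient_id"])
    cl = clinical[clinical["qc_pass"]] if "qc_pass" in clinical.columns else clinical
    mut = cl[cl["patient_id"].isin(carriers)]["age"].to_numpy()
    non = cl[~cl["patient_id"].isin(carriers)]["age"].to_numpy()
    _, p = mann_whitney_one_tailed(mut, non)
    return float(mut.mean() - non.mean()), p


def end_to_end_recovery(config: SimulationConfig, seeds: Sequence[int],
                        render_patients: int = 2,
                        tmp_dir: Optional[Path] = None) -> pd.DataFrame:
    """Run simulate -> (render -> ingest ->) nominate -> stats per seed.

    Full VCF rendering + re-ingestion runs for ``render_patients`` mutated
    patients per seed (checking round-trip and identity); label recovery and
    the age-shift estimate use the whole truth table.  Returns one row per
    seed with recovery metrics.
    """
    import tempfile
    from . import variant_io as vio
    from .identity import genotype_snp_loci, trio_concordance, Verdict
    from .nomination import default_knowledge_base, nominate

    kb = default_knowledge_base()
    rows = []
    for seed in seeds:
        sim = CohortSimulator(replace(config, seed=int(seed)))
        clinical, truth = sim.simulate_cohort()
        shift, age_p = estimate_age_shift(clinical, truth)
        # rule recovery against truth labels
        n_match = 0
        for rec in truth.itertuples(index=False):
            nm = nominate(rec.patient_id, rec.gene, rec.protein_change, kb)
            n_match += (nm.label.value == rec.expected_label)
        recovery = n_match / len(truth) if len(truth) else float("nan")

        identity_pass = float("nan")
        roundtrip_ok = True
        if render_patients:
            with tempfile.TemporaryDirectory(dir=tmp_dir) as td:
                pids = truth["patient_id"].drop_duplicates().head(render_patients)
                verdicts = []
                for pid in pids:
                    paths = sim.render_trio_vcfs(pid, truth[truth["patient_id"] == pid], td)
                    trio_genos = {}
                    for frac in ("germline", "cell_pellet", "cfdna"):
                        calls = vio.read_caller_vcf(paths[(frac, "mutect")], pid,
                                                    vio.Fraction(frac), "mutect")
                        obs = _snp_observations(calls, sim.snps)
                        trio_genos[vio.Fraction(frac)] = genotype_snp_loci(obs)
                    verdicts.append(trio_concordance(trio_genos, pid).verdict)
                identity_pass = float(np.mean([v is Verdict.MATCH for v in verdicts]))
        rows.append({"seed": int(seed), "age_shift": shift, "age_p": age_p,
                     "label_recovery": recovery, "identity_pass": identity_pass,
                     "n_truth_mutations": len(truth)})
    return pd.DataFrame(rows)


def _snp_observations(calls, snps: pd.DataFrame) -> Dict[str, Tuple[int, int]]:
    by_pos = {(str(r.chrom), int(r.pos)): str(r.locus_id)
              for r in snps.itertuples(index=False)}
    obs: Dict[str, Tuple[int, int]] = {}
    for c in calls:
        locus = by_pos.get((c.chrom, c.pos))
        if locus is not None:
            obs[locus] = (c.depth, c.alt_reads)
    return obs
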