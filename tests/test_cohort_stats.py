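"""AF binning, concordance, enrichment and association statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from lavagemut import cohort as ch
from lavagemut.cohort import (AssociationResult, CohortAnalysis, DataError,
                              bh_adjust, bin_by_allele_fraction, bin_label,
                              bin_enrichment_test, cancer_fraction_by_bin,
                              clinical_association_scan, fisher_exact_2x2,
                              fraction_concordance, gene_sum_correlation,
                              mann_whitney_one_tailed, one_sided_location_ci,
                              summarize_bin_patients)


def mutations_from_published(table: pd.DataFrame) -> pd.DataFrame:
    """Expand the published per-gene bin counts into one row per mutation,
    with a representative AF inside each bin."""
    rep_af = {"low": 0.03, "mid": 0.08, "high": 0.15}
    rows = []
    i = 0
    for r in table.itertuples(index=False):
        for frac, prefix in (("cell_pellet", "pellet"), ("cfdna", "cfdna")):
            for b in ("low", "mid", "high"):
                for _ in range(int(getattr(r, f"{prefix}_{b}"))):
                    rows.append({"patient_id": f"P{i}", "gene": r.gene,
                                 "protein_change": f"M{i}V", "fraction": frac,
                                 "allele_fraction": rep_af[b]})
                    i += 1
    return pd.DataFrame(rows)


class TestBinning:
    def test_boundary_convention(self):
        assert bin_label(0.05) == "low"      # "<=5.00%" label
        assert bin_label(0.0501) == "mid"
        assert bin_label(0.10) == "mid"      # "5.01%-10.00%"
        assert bin_label(0.1001) == "high"

    @pytest.mark.parametrize("af", [0.0, -0.1, 1.5])
    def test_af_outside_domain_is_error(self, af):
        with pytest.raises(DataError):
            bin_label(af)

    def test_uniform_afs_match_brute_force(self):
        rng = np.random.default_rng(2)
        afs = rng.uniform(0.001, 1.0, size=1000)
        afs = afs[afs > 0]
        df = pd.DataFrame({"patient_id": "P", "gene": "PTEN",
                           "fraction": "cell_pellet", "allele_fraction": afs})
        table = bin_by_allele_fraction(df)
        brute = {"low": 0, "mid": 0, "high": 0}
        for af in afs:
            if af <= 0.05:
                brute["low"] += 1
            elif af <= 0.10:
                brute["mid"] += 1
            else:
                brute["high"] += 1
        for b, n in brute.items():
            assert table.counts.loc["PTEN", ("cell_pellet", b)] == n

    def test_published_row_sums_reassemble(self, published_af_table):
        df = mutations_from_published(published_af_table)
        table = bin_by_allele_fraction(df)
        for r in published_af_table.itertuples(index=False):
            assert table.gene_sums("cell_pellet")[r.gene] == \
                r.pellet_low + r.pellet_mid + r.pellet_high
            assert table.gene_sums("cfdna")[r.gene] == \
                r.cfdna_low + r.cfdna_mid + r.cfdna_high
        # the worked example: PTEN pellet 17+1+4 = 22
        assert table.gene_sums("cell_pellet")["PTEN"] == 22


class TestGeneSumCorrelation:
    def test_published_sums_give_r2_092(self, published_af_table):
        t = published_af_table
        pellet = (t.pellet_low + t.pellet_mid + t.pellet_high).to_numpy()
        cfdna = (t.cfdna_low + t.cfdna_mid + t.cfdna_high).to_numpy()
        _, r2 = gene_sum_correlation(pellet, cfdna)
        assert round(r2, 2) == 0.92

    def test_identical_vectors_give_unity(self):
        _, r2 = gene_sum_correlation([1, 5, 9, 2], [1, 5, 9, 2])
        assert r2 == pytest.approx(1.0)

    def test_matches_from_definition_formula(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=12), rng.normal(size=12)
        r, r2 = gene_sum_correlation(x, y)
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        r_def = cov / (x.std() * y.std())
        assert abs(r - r_def) < 1e-12

    def test_symmetric_under_swap(self):
        rng = np.random.default_rng(9)
        x, y = rng.poisson(5, 10), rng.poisson(5, 10)
        assert gene_sum_correlation(x, y) == gene_sum_correlation(y, x)

    def test_zero_variance_flagged_as_nan(self):
        r, r2 = gene_sum_correlation([3, 3, 3], [1, 2, 3])
        assert math.isnan(r) and math.isnan(r2)


class TestCancerFractionByBin:
    def test_published_patient_counts_give_printed_percentages(
            self, published_bin_patients):
        out = summarize_bin_patients(published_bin_patients)
        expect = {("cell_pellet", "low"): 9, ("cell_pellet", "mid"): 27,
                  ("cell_pellet", "high"): 50, ("cfdna", "low"): 15,
                  ("cfdna", "mid"): 25, ("cfdna", "high"): 75}
        for r in out.itertuples(index=False):
            assert r.percent == expect[(r.fraction, r.bin)]

    def test_all_cancer_cohort_gives_100_in_occupied_bins(self):
        muts = pd.DataFrame({
            "patient_id": ["P1", "P2", "P3"], "gene": "PTEN",
            "fraction": "cfdna", "allele_fraction": [0.02, 0.08, 0.2]})
        clinical = pd.DataFrame({"patient_id": ["P1", "P2", "P3"],
                                 "cancer": [True, True, True]})
        out = cancer_fraction_by_bin(muts, clinical)
        occupied = out[out["total_patients"] > 0]
        assert (occupied["percent"] == 100).all()

    def test_empty_bin_reported_na(self):
        muts = pd.DataFrame({"patient_id": ["P1"], "gene": ["PTEN"],
                             "fraction": ["cfdna"], "allele_fraction": [0.02]})
        clinical = pd.DataFrame({"patient_id": ["P1"], "cancer": [False]})
        out = cancer_fraction_by_bin(muts, clinical).set_index(["fraction", "bin"])
        assert out.loc[("cfdna", "high"), "percent"] is pd.NA


def enumerate_fisher_two_sided(table):
    """Full hypergeometric enumeration with fixed margins (oracle)."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestFisher:
    def test_identical_rows_give_p_one(self):
        assert fisher_exact_2x2([[5, 3], [5, 3]]) == pytest.approx(1.0)

    def test_extreme_table_closed_form(self):
        # [[10,0],[0,10]]: only the two extreme tables are as improbable
        p = fisher_exact_2x2([[10, 0], [0, 10]])
        assert p == pytest.approx(2 / math.comb(20, 10))

    def test_spec_example_against_enumeration(self):
        t = [[3, 1], [6, 31]]
        assert fisher_exact_2x2(t) == pytest.approx(enumerate_fisher_two_sided(t))

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [2, 3]])

    def test_one_sided_alternatives(self):
        t = [[8, 2], [2, 8]]
        assert fisher_exact_2x2(t, "greater") < fisher_exact_2x2(t, "less")


def enumerate_mww_one_sided(a, b):
    """Exact permutation enumeration of the one-sided Mann-Whitney p (oracle)."""
    pooled = list(a) + list(b)
    n_a = len(a)

    def u_stat(xs, ys):
        return sum((x > y) + 0.5 * (x == y) for x in xs for y in ys)

    u_obs = u_stat(a, b)
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n_a):
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in range(len(pooled)) if i not in comb]
        total += 1
        if u_stat(xs, ys) >= u_obs - 1e-9:
            count += 1
    return count / total


class TestMannWhitney:
    def test_extreme_ordering_closed_form(self):
        # all of b above a; one-sided p for "b greater" = 1 / C(6,3)
        _, p = mann_whitney_one_tailed([4, 5, 6], [1, 2, 3])
        assert p == pytest.approx(1 / math.comb(6, 3))

    def test_matches_exact_permutation_enumeration(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            a = rng.normal(size=8)
            b = rng.normal(size=7)
            _, p = mann_whitney_one_tailed(a, b)
            assert p == pytest.approx(enumerate_mww_one_sided(a, b), abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_one_tailed([], [1.0])


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.037]) == [pytest.approx(0.037)]

    def test_hand_application_of_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_output_dominates_input_and_capped(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=25)
        q = bh_adjust(p)
        assert all(qi >= pi for qi, pi in zip(q, p))
        assert all(qi <= 1 for qi in q)

    def test_matches_step_up_formula_oracle(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=15)
        m = len(p)
        order = np.argsort(p)
        q_sorted = np.minimum.accumulate(
            (p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(q_sorted, 1)
        assert bh_adjust(p) == pytest.approx(list(oracle))

    def test_order_invariance(self):
        p = [0.3, 0.01, 0.7, 0.04]
        q = bh_adjust(p)
        q_rev = bh_adjust(p[::-1])
        assert q == pytest.approx(q_rev[::-1])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestLocationCI:
    def test_identical_constant_groups_bound_zero(self):
        assert one_sided_location_ci([5.0] * 10, [5.0] * 10, seed=0) == 0.0

    def test_large_sample_matches_z_bound(self):
        rng = np.random.default_rng(12)
        a = rng.normal(10, 2, size=2000)
        b = rng.normal(7, 2, size=2000)
        bound = one_sided_location_ci(a, b, seed=1)
        se = math.sqrt(a.var() / a.size + b.var() / b.size)
        z_bound = (a.mean() - b.mean()) - 1.6449 * se
        assert bound == pytest.approx(z_bound, abs=3 * se / 10)

    def test_seeded_determinism(self):
        a, b = [1.0, 2, 3, 4], [0.5, 1.5, 2.5]
        assert one_sided_location_ci(a, b, seed=7) == one_sided_location_ci(a, b, seed=7)


class TestEnrichment:
    def test_planted_high_af_cancer_enrichment_detected(self):
        rng = np.random.default_rng(21)
        rows, cancer = [], {}
        for i in range(60):
            pid = f"P{i}"
            is_cancer = i < 8
            cancer[pid] = is_cancer
            af = rng.uniform(0.11, 0.3) if is_cancer else rng.uniform(0.011, 0.05)
            rows.append({"patient_id": pid, "gene": "PTEN", "fraction": "cfdna",
                         "allele_fraction": af})
        clinical = pd.DataFrame({"patient_id": list(cancer), "cancer": list(cancer.values())})
        p = bin_enrichment_test(pd.DataFrame(rows), clinical, "cfdna")
        assert p < 0.01

    def test_single_patient_cohort_is_na(self):
        muts = pd.DataFrame({"patient_id": ["P1"], "gene": ["PTEN"],
                             "fraction": ["cfdna"], "allele_fraction": [0.2]})
        clinical = pd.DataFrame({"patient_id": ["P1"], "cancer": [True]})
        assert bin_enrichment_test(muts, clinical, "cfdna") is None


class TestAssociationScan:
    def _cohort(self, shift, n=50, m=52, seed=0):
        rng = np.random.default_rng(seed)
        status = {}
        rows = []
        for i in range(n + m):
            pid = f"P{i}"
            mutated = i < n
            status[pid] = mutated
            rows.append({
                "patient_id": pid,
                "age": rng.normal(50.35 + (shift if mutated else 0), 11),
                "bmi": rng.normal(28, 6), "parity": int(rng.integers(0, 4)),
                "menopausal": bool(rng.random() < 0.5),
                "diabetes": bool(rng.random() < 0.15),
                "smoking": rng.choice(["never", "former", "current"]),
                "race": rng.choice(["white", "asian", "other"]),
            })
        return pd.DataFrame(rows), status

    def test_planted_age_shift_detected(self):
        clinical, status = self._cohort(shift=7.61, seed=3)
        results = clinical_association_scan(clinical, status, seed=3)
        by_cov = {r.covariate: r for r in results}
        assert by_cov["age"].p_raw < 0.05
        assert by_cov["age"].p_adjusted >= by_cov["age"].p_raw
        assert by_cov["age"].mean_positive > by_cov["age"].mean_negative

    def test_independent_covariates_not_flagged_en_masse(self):
        clinical, status = self._cohort(shift=0.0, seed=5)
        results = clinical_association_scan(clinical, status, seed=5)
        assert sum(r.p_adjusted < 0.05 for r in results) == 0

    def test_degenerate_all_mutated_cohort(self):
        clinical, status = self._cohort(shift=5)
        status = {k: True for k in status}
        results = clinical_association_scan(clinical, status)
        assert all(r.test == "NA" for r in results)


class TestFractionConcordance:
    def test_three_way_partition(self):
        muts = pd.DataFrame([
            {"patient_id": "P1", "gene": "PTEN", "protein_change": "R130G",
             "fraction": "cell_pellet", "allele_fraction": 0.02},
            {"patient_id": "P1", "gene": "PTEN", "protein_change": "R130G",
             "fraction": "cfdna", "allele_fraction": 0.03},
            {"patient_id": "P1", "gene": "KRAS", "protein_change": "G12D",
             "fraction": "cell_pellet", "allele_fraction": 0.02},
            {"patient_id": "P2", "gene": "TP53", "protein_change": "C176F",
             "fraction": "cfdna", "allele_fraction": 0.05},
        ])
        out = fraction_concordance(muts)
        assert out["partition"] == {"both": 1, "pellet_only": 1, "cfdna_only": 1}
        per_gene = out["per_gene"].set_index("gene")
        assert per_gene.loc["PTEN", "unique_patients"] == 1

    def test_synthetic_truth_partition_recovered(self, cohort_seed11):
        clinical, truth = cohort_seed11
        rows = []
        for r in truth.itertuples(index=False):
            for frac, flag in (("cell_pellet", r.in_pellet), ("cfdna", r.in_cfdna)):
                if flag:
                    rows.append({"patient_id": r.patient_id, "gene": r.gene,
                                 "protein_change": r.protein_change,
                                 "fraction": frac, "allele_fraction": r.af})
        out = fraction_concordance(pd.DataFrame(rows))
        truth_both = int((truth.in_pellet & truth.in_cfdna).sum())
        truth_pellet = int((truth.in_pellet & ~truth.in_cfdna).sum())
        truth_cfdna = int((~truth.in_pellet & truth.in_cfdna).sum())
        assert out["partition"] == {"both": truth_both, "pellet_only": truth_pellet,
                                    "cfdna_only": truth_cfdna}


def test_cohort_analysis_fit_and_summary(cohort_seed11, kb):
    from lavagemut.nomination import nominate_frame, nominations_to_frame
    clinical, truth = cohort_seed11
    rows = []
    for r in truth.itertuples(index=False):
        for frac, flag in (("cell_pellet", r.in_pellet), ("cfdna", r.in_cfdna)):
            if flag:
                rows.append({"patient_id": r.patient_id, "gene": r.gene,
                             "protein_change": r.protein_change, "fraction": frac,
                             "allele_fraction": r.af,
                             "label": r.expected_label})
    model = CohortAnalysis(pd.DataFrame(rows), clinical)
    res = model.fit(seed=0)
    assert 0 <= res.r_squared <= 1
    text = res.summary()
    assert "r^2" in text and "Clinical associations" in text
    assert (res.association_frame()["p_bh"] >= res.association_frame()["p_raw"] - 1e-12).all()
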