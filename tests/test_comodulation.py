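"""Anchor-vs-partner exact tests, ratios, cutoffs and the full analysis."""

import math
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy.stats import fisher_exact

from comodnet.comodulation import (AnchorNotFoundError, ComodConfig,
                                   categorize_partner, comod_ratio,
                                   condition_set_overlap, fisher_one_sided,
                                   high_confidence_cutoff, redundancy_support,
                                   run_comodulation)
from comodnet.cooccurrence import PairCounts
from comodnet.corpus import SiteKey
from comodnet.qc import direction_matrix
from comodnet.simulate import (GeneratorConfig, PlantedPartner, generate_corpus)

from helpers import make_corpus

ANCHOR = SiteKey("P07947", "YES1", "Y", 426)


def enumeration_p(a: int, b: int, c: int, d: int, alternative: str) -> Fraction:
    """Independent oracle: exact tail mass by enumerating all tables with the
    observed margins, in rational arithmetic."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return Fraction(1)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    total = Fraction(0)
    for k in range(lo, hi + 1):
        if (alternative == "concordant" and k >= a) or (alternative == "discordant" and k <= a):
            total += Fraction(comb(r1, k) * comb(n - r1, c1 - k), comb(n, c1))
    return total


class TestFisherOneSided:
    def test_perfectly_concordant_worked_example(self):
        # margins (3,3)/(3,3): only one table attains the (I,I) cell 3,
        # p = C(3,3)C(3,0)/C(6,3) = 1/20
        assert fisher_one_sided(PairCounts(3, 0, 0, 3), "concordant") == pytest.approx(0.05)

    def test_empty_table_is_one(self):
        assert fisher_one_sided(PairCounts(0, 0, 0, 0), "concordant") == 1.0
        assert fisher_one_sided(PairCounts(0, 0, 0, 0), "discordant") == 1.0

    def test_zero_margin_is_one(self):
        assert fisher_one_sided(PairCounts(3, 2, 0, 0), "concordant") == 1.0
        assert fisher_one_sided(PairCounts(0, 4, 0, 6), "concordant") == 1.0

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            fisher_one_sided(PairCounts(-1, 0, 0, 0), "concordant")

    def test_unknown_alternative_rejected(self):
        with pytest.raises(ValueError):
            fisher_one_sided(PairCounts(1, 1, 1, 1), "two-sided")

    def test_matches_enumeration_oracle_small_margins(self):
        """Exact agreement with rational-arithmetic enumeration, both tails."""
        for a in range(0, 7):
            for b in range(0, 7):
                for c in range(0, 7):
                    for d in range(0, 7):
                        for alt in ("concordant", "discordant"):
                            got = fisher_one_sided(PairCounts(a, b, c, d), alt)
                            want = float(enumeration_p(a, b, c, d, alt))
                            assert got == pytest.approx(want, abs=1e-12), (a, b, c, d, alt)

    def test_matches_scipy_fisher_exact(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 20, size=4)
            table = [[a, b], [c, d]]
            assert fisher_one_sided(PairCounts(a, b, c, d), "concordant") == pytest.approx(
                fisher_exact(table, alternative="greater")[1], rel=1e-9)
            assert fisher_one_sided(PairCounts(a, b, c, d), "discordant") == pytest.approx(
                fisher_exact(table, alternative="less")[1], rel=1e-9)


class TestRatioAndCutoff:
    @pytest.mark.parametrize("counts,sign,expected", [
        (PairCounts(8, 1, 1, 2), "positive", 5.0),
        (PairCounts(0, 4, 4, 0), "negative", math.inf),
        (PairCounts(1, 1, 1, 1), "positive", 1.0),
    ])
    def test_worked_ratios(self, counts, sign, expected):
        assert comod_ratio(counts, sign) == expected

    @pytest.mark.parametrize("n,frac,expected", [(72, 0.10, 7.2), (10, 0.10, 1.0), (1, 0.10, 0.1)])
    def test_cutoff_rule(self, n, frac, expected):
        assert high_confidence_cutoff(n, frac) == pytest.approx(expected)

    @pytest.mark.parametrize("n,frac", [(0, 0.1), (-3, 0.1), (10, 0.0), (10, -0.5)])
    def test_cutoff_invalid_inputs(self, n, frac):
        with pytest.raises(ValueError):
            high_confidence_cutoff(n, frac)


class TestCategorizeAndSupport:
    def test_anchor_in_two_partner_split(self):
        corpus = make_corpus({
            ("P07947", "YES1", "Y", 426): {"d1": "increased", "d2": "increased"},
            ("P2", "G2", "S", 5): {"d1": "increased", "d2": "decreased"},
        })
        dirs = direction_matrix(corpus)
        counts = categorize_partner(ANCHOR, SiteKey("P2", "G2", "S", 5), dirs)
        assert counts == PairCounts(1, 1, 0, 0)

    def test_partner_on_anchor_protein_rejected(self):
        corpus = make_corpus({("P07947", "YES1", "Y", 426): {"d1": "increased"}})
        with pytest.raises(ValueError, match="anchor protein"):
            categorize_partner(ANCHOR, SiteKey("P07947", "YES1", "T", 427),
                               direction_matrix(corpus))

    def test_never_co_callable_is_all_zero(self):
        corpus = make_corpus({
            ("P07947", "YES1", "Y", 426): {"d1": "increased"},
            ("P2", "G2", "S", 5): {"d2": "increased"},
        })
        counts = categorize_partner(ANCHOR, SiteKey("P2", "G2", "S", 5),
                                    direction_matrix(corpus))
        assert counts == PairCounts(0, 0, 0, 0)

    def test_redundancy_counts_distinct_studies_and_conditions(self):
        plan = {f"d{i}": "increased" for i in range(4)}
        corpus = make_corpus(
            {("P07947", "YES1", "Y", 426): plan, ("P2", "G2", "S", 5): plan},
            studies={"d0": "s1", "d1": "s1", "d2": "s2", "d3": "s2"},
            conditions={f"d{i}": f"c{i}" for i in range(4)},
        )
        dirs = direction_matrix(corpus)
        support = redundancy_support(SiteKey("P2", "G2", "S", 5), ANCHOR, dirs)
        assert support == (2, 4)  # fails the default >=3-studies rule

    def test_no_contributing_dataset_support_zero(self):
        corpus = make_corpus({
            ("P07947", "YES1", "Y", 426): {"d1": "increased"},
            ("P2", "G2", "S", 5): {"d2": "increased"},
        })
        dirs = direction_matrix(corpus)
        assert redundancy_support(SiteKey("P2", "G2", "S", 5), ANCHOR, dirs) == (0, 0)


def _ten_dataset_corpus():
    """Anchor callable in 10 datasets (6 up / 4 down); one perfectly
    concordant partner, one balanced partner; 3 studies x 5 conditions."""
    anchor_plan = {f"d{i}": ("increased" if i < 6 else "decreased") for i in range(10)}
    balanced = {"d0": "increased", "d1": "decreased", "d6": "increased", "d7": "decreased"}
    return make_corpus(
        {
            ("P07947", "YES1", "Y", 426): anchor_plan,
            ("P2", "CONC", "S", 5): dict(anchor_plan),
            ("P3", "BAL", "T", 9): balanced,
        },
        studies={f"d{i}": f"s{i % 3}" for i in range(10)},
        conditions={f"d{i}": f"c{i % 5}" for i in range(10)},
    )


class TestRunComodulation:
    def test_perfect_partner_counts_p_ratio_and_confidence(self):
        result = run_comodulation(_ten_dataset_corpus(), ANCHOR)
        assert result.n_anchor_datasets == 10
        assert result.cutoff == pytest.approx(1.0)
        row = result.table[result.table["gene"] == "CONC"].iloc[0]
        assert (row["n_cc"], row["n_cd"], row["n_dc"], row["n_dd"]) == (6, 0, 0, 4)
        assert row["p_positive"] == pytest.approx(float(enumeration_p(6, 0, 0, 4, "concordant")))
        assert row["p_positive"] == pytest.approx(1 / comb(10, 6))
        assert math.isinf(row["ratio_positive"])
        assert row["sign_class"] == "positive"
        assert bool(row["high_confidence"])

    def test_balanced_partner_has_no_sign(self):
        result = run_comodulation(_ten_dataset_corpus(), ANCHOR)
        row = result.table[result.table["gene"] == "BAL"].iloc[0]
        assert (row["n_cc"], row["n_cd"], row["n_dc"], row["n_dd"]) == (1, 1, 1, 1)
        assert row["sign_class"] == "none"
        assert not row["high_confidence"]

    def test_missing_anchor_raises(self):
        with pytest.raises(AnchorNotFoundError):
            run_comodulation(_ten_dataset_corpus(), SiteKey("P07947", "YES1", "Y", 999))

    def test_q_values_bound_raw_p(self):
        table = run_comodulation(_ten_dataset_corpus(), ANCHOR).table
        assert ((table["bh_q_value"] >= table[["p_positive", "p_negative"]].min(axis=1) - 1e-12)
                & (table["bh_q_value"] <= 1)).all()

    def test_strongly_concordant_partners_recovered(self):
        """Near-deterministic planted partners are found as high-confidence
        positives and independent background stays clean (generator sanity)."""
        partners = [PlantedPartner(SiteKey(f"Q{i:04d}", f"PP{i}", "S", 10 + i),
                                   concordance=0.99, coobservation_probability=0.8)
                    for i in range(15)]
        config = GeneratorConfig(planted_partners=partners, n_background_sites=100,
                                 n_profile_datasets=0, seed=5)
        corpus, truth = generate_corpus(config)
        result = run_comodulation(corpus, ANCHOR)
        hc_pos = result.high_confidence_sites("positive")
        planted = {(p.site.accession, p.site.residue, p.site.position) for p in partners}
        assert len(planted & hc_pos) >= 14
        assert all(not acc.startswith("B") for acc, _, _ in hc_pos)

    def test_tallies_match_generator_truth(self, fixture_corpus, fixture_truth, anchor):
        dirs = direction_matrix(fixture_corpus)
        for site, sign in fixture_truth.planted_sign.items():
            acc, respos = site.split(":")
            counts = categorize_partner(
                anchor, SiteKey(acc, "", respos[0], int(respos[1:])), dirs)
            assert list(counts) == fixture_truth.expected_pair_counts[site]


class TestConditionSetOverlap:
    def test_counts_match_brute_force_sets(self):
        corpus = _ten_dataset_corpus()
        result = run_comodulation(corpus, ANCHOR)
        overlap = condition_set_overlap(result, corpus, [["c0"], ["c0", "c1"], ["c4"]])
        # CONC co-callable with the anchor in all 10 datasets -> all 5 codes
        assert overlap.set_index("conditions")["n_common_partners"].to_dict() == {
            "c0": 1, "c0;c1": 1, "c4": 1}

    def test_disjoint_supports_zero(self):
        corpus = _ten_dataset_corpus()
        result = run_comodulation(corpus, ANCHOR)
        # BAL only ever overlaps codes c0..c2 and is not high-confidence anyway
        counts = condition_set_overlap(result, corpus, [["c2", "c3"]])
        assert counts.iloc[0]["n_common_partners"] == 1  # CONC still covers both

    def test_unknown_code_lists_known(self):
        corpus = _ten_dataset_corpus()
        result = run_comodulation(corpus, ANCHOR)
        with pytest.raises(ValueError, match="unknown condition code"):
            condition_set_overlap(result, corpus, [["nope"]])


class TestFilterMonotonicity:
    @pytest.mark.parametrize("stricter", [
        ComodConfig(min_studies=5), ComodConfig(cutoff_fraction=0.20),
        ComodConfig(min_conditions=5), ComodConfig(alpha=0.01),
    ])
    def test_tightening_never_adds_partners(self, fixture_corpus, anchor, stricter):
        base = run_comodulation(fixture_corpus, anchor).high_confidence_sites()
        tight = run_comodulation(fixture_corpus, anchor, config=stricter).high_confidence_sites()
        assert tight <= base
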