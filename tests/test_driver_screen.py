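import numpy as np
import pytest

from syndriver import driver_screen
from syndriver.driver_screen import ThresholdSet
from syndriver.variant_io import GeneSetCollection, VariantRecord

from .oracles import driver_filter_oracle, gene_group_oracle


def variant(pos=1, gene="G1", patient="P1", effect=None, gerp=None, synmicdb=None,
            pop_freq=None, alt="G", consequence="synonymous"):
    scores = {}
    if effect is not None:
        scores["effect_score"] = effect
    if gerp is not None:
        scores["gerp"] = gerp
    if synmicdb is not None:
        scores["synmicdb_score"] = synmicdb
    if pop_freq is not None:
        scores["pop_freq"] = pop_freq
    return VariantRecord(
        chrom="1",
        pos=pos,
        ref="A",
        alt=alt,
        gene=gene,
        transcript="T_" + gene,
        patient_id=patient,
        consequence=consequence,
        scores=scores,
    )


CANCER = GeneSetCollection(sets={"CGC": frozenset({"G1", "G2"})})


class TestReferenceSelection:
    def test_percentile_cut_on_1_to_100(self):
        variants = [variant(pos=i, synmicdb=float(i)) for i in range(1, 101)]
        ref = driver_screen.select_reference_set(variants, 95)
        # interpolated 95th percentile of 1..100 is 95.05
        assert sorted(v.scores["synmicdb_score"] for v in ref) == [96, 97, 98, 99, 100]

    def test_all_equal_scores_all_kept(self):
        variants = [variant(pos=i, synmicdb=7.0) for i in range(1, 11)]
        assert len(driver_screen.select_reference_set(variants)) == 10

    def test_single_variant_kept(self):
        assert len(driver_screen.select_reference_set([variant(synmicdb=1.0)])) == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            driver_screen.select_reference_set([])

    def test_missing_score_rejected(self):
        with pytest.raises(ValueError, match="synmicdb"):
            driver_screen.select_reference_set([variant()])


class TestDeriveThresholds:
    def test_odd_length_median(self):
        ref = [
            variant(pos=1, effect=0.5, gerp=1.0),
            variant(pos=2, effect=0.81, gerp=2.0),
            variant(pos=3, effect=0.9, gerp=3.0),
        ]
        assert driver_screen.derive_thresholds(ref).tau_effect == pytest.approx(0.81)

    def test_even_length_median_is_central_mean(self):
        ref = [variant(pos=1, effect=0.5, gerp=2.0), variant(pos=2, effect=0.6, gerp=2.62)]
        assert driver_screen.derive_thresholds(ref).tau_cons == pytest.approx(2.31)

    def test_matches_sort_and_index_oracle(self):
        rng = np.random.default_rng(2)
        scores = rng.uniform(size=1001)
        ref = [variant(pos=i + 1, effect=float(s), gerp=float(s) * 5) for i, s in enumerate(scores)]
        tau = driver_screen.derive_thresholds(ref).tau_effect
        assert tau == pytest.approx(sorted(scores)[500], abs=1e-15)

    def test_missing_scores_listed(self):
        with pytest.raises(ValueError, match="missing"):
            driver_screen.derive_thresholds([variant(effect=0.5)])


class TestRecurrence:
    def test_same_patient_twice_is_not_recurrent(self):
        counts = driver_screen.tag_recurrent([variant(patient="P1"), variant(patient="P1")])
        assert counts[("1", 1, "A", "G")] == 1

    def test_two_distinct_patients_is_recurrent(self):
        counts = driver_screen.tag_recurrent([variant(patient="P1"), variant(patient="P2")])
        assert counts[("1", 1, "A", "G")] == 2

    def test_hand_tallied_fixture(self):
        rows = []
        tally = {}
        rng = np.random.default_rng(6)
        for _ in range(20):
            pos = int(rng.integers(1, 8))
            patient = f"P{rng.integers(1, 5)}"
            rows.append(variant(pos=pos, patient=patient))
            tally.setdefault(("1", pos, "A", "G"), set()).add(patient)
        counts = driver_screen.tag_recurrent(rows)
        assert counts == {k: len(v) for k, v in tally.items()}


class TestDriverFilters:
    TAU = ThresholdSet(tau_effect=0.81, tau_cons=2.31, reference_size=25)

    def _flags(self, rows):
        res = driver_screen.apply_driver_filters(rows, self.TAU, CANCER)
        return res.variants.iloc[0]

    def test_all_criteria_met_is_proposed(self):
        rows = [variant(effect=0.82, gerp=2.4, patient=f"P{i}") for i in range(3)]
        assert self._flags(rows)["is_proposed_driver"]

    def test_effect_exactly_at_threshold_fails(self):
        rows = [variant(effect=0.81, gerp=2.4, patient=f"P{i}") for i in range(3)]
        row = self._flags(rows)
        assert not row["passed_effect"] and not row["is_proposed_driver"]

    def test_gerp_exactly_at_threshold_fails(self):
        rows = [variant(effect=0.9, gerp=2.31, patient=f"P{i}") for i in range(3)]
        assert not self._flags(rows)["passed_conservation"]

    def test_non_cancer_gene_fails_membership(self):
        rows = [variant(gene="GX", effect=0.9, gerp=3.0, patient=f"P{i}") for i in range(2)]
        row = self._flags(rows)
        assert not row["passed_cancer_gene"] and not row["is_proposed_driver"]

    def test_missing_scores_indeterminate(self):
        rows = [variant(patient=f"P{i}") for i in range(3)]
        row = self._flags(rows)
        assert row["indeterminate"] and not row["is_proposed_driver"]

    def test_matches_brute_force_oracle_on_cohort(self, small_cohort):
        syn = [
            v
            for v in small_cohort.variants
            if v.category == "somatic_cancer" and v.consequence == "synonymous"
        ]
        tau = small_cohort.truth.thresholds
        res = driver_screen.apply_driver_filters(syn, tau, small_cohort.gene_sets)
        got = {
            (r.chrom, r.pos, r.ref, r.alt)
            for r in res.variants[res.variants["is_proposed_driver"]].itertuples()
        }
        want = driver_filter_oracle(
            syn, tau.tau_effect, tau.tau_cons, small_cohort.gene_sets.union()
        )
        assert got == want

    def test_cascade_monotone_and_order_invariant(self, small_cohort):
        syn = [
            v
            for v in small_cohort.variants
            if v.category == "somatic_cancer" and v.consequence == "synonymous"
        ]
        tau = small_cohort.truth.thresholds
        res = driver_screen.apply_driver_filters(syn, tau, small_cohort.gene_sets)
        log = res.log
        assert (
            log["n_keys"]
            >= log["after_recurrence"]
            >= log["after_recurrence_conservation"]
            >= log["after_recurrence_conservation_effect"]
            >= log["proposed_drivers"]
        )
        # order invariance: intersecting the per-filter flag columns in any
        # order yields the same driver set
        t = res.variants
        flags = ["passed_recurrence", "passed_conservation", "passed_effect", "passed_cancer_gene"]
        base = t[flags[0]] & t[flags[1]] & t[flags[2]] & t[flags[3]] & ~t["indeterminate"]
        perm = t[flags[3]] & t[flags[1]] & t[flags[0]] & t[flags[2]] & ~t["indeterminate"]
        assert (base == t["is_proposed_driver"]).all()
        assert (perm == t["is_proposed_driver"]).all()


class TestGeneGroups:
    TAU = ThresholdSet(tau_effect=0.81, tau_cons=2.31, reference_size=25)

    def test_only_non_recurrent_variants_is_group_one(self):
        rows = [variant(pos=i, effect=0.9, gerp=3.0) for i in (1, 2, 3)]
        table = driver_screen.classify_gene_groups(rows, self.TAU)
        assert table.iloc[0]["group"] == 1

    def test_recurrent_conserved_high_effect_is_group_four(self):
        rows = [variant(effect=0.9, gerp=3.0, patient=f"P{i}") for i in range(2)]
        table = driver_screen.classify_gene_groups(rows, self.TAU)
        assert table.iloc[0]["group"] == 4

    def test_matches_brute_force_oracle(self, small_cohort):
        syn = [v for v in small_cohort.variants if v.category == "somatic_cancer"]
        tau = small_cohort.truth.thresholds
        table = driver_screen.classify_gene_groups(syn, tau)
        want = gene_group_oracle(syn, tau.tau_effect, tau.tau_cons)
        got = dict(zip(table["gene"], table["group"]))
        assert got == want

    def test_groups_are_nested(self, small_cohort):
        syn = [v for v in small_cohort.variants if v.category == "somatic_cancer"]
        table = driver_screen.classify_gene_groups(syn, small_cohort.truth.thresholds)
        for row in table.itertuples():
            assert row.n_total >= row.n_recurrent >= row.n_recurrent_conserved
            assert row.n_recurrent_conserved >= row.n_recurrent_conserved_effect
            if row.group == 1:
                assert row.n_recurrent == 0
            else:
                assert getattr(
                    row,
                    {
                        2: "n_recurrent",
                        3: "n_recurrent_conserved",
                        4: "n_recurrent_conserved_effect",
                    }[row.group],
                ) > 0

    def test_driver_containing_genes_are_group_four(self, small_cohort):
        # consistency with the variant-level screen: a gene with a proposed
        # driver (which is recurrent, conserved, high-effect) must be group 4
        syn = [
            v
            for v in small_cohort.variants
            if v.category == "somatic_cancer" and v.consequence == "synonymous"
        ]
        tau = small_cohort.truth.thresholds
        res = driver_screen.apply_driver_filters(syn, tau, small_cohort.gene_sets)
        groups = dict(zip(res.genes["gene"], res.genes["group"]))
        for r in res.variants[res.variants["is_proposed_driver"]].itertuples():
            assert groups[r.gene] == 4


class TestPercentileSelect:
    WORKED = {"WG%02d" % (i + 1): c for i, c in enumerate((1, 1, 2, 2, 3, 3, 3, 3, 8, 9))}

    def test_worked_example_selects_counts_eight_and_nine(self):
        selected = driver_screen.percentile_select(self.WORKED, 70)
        assert sorted(self.WORKED[g] for g in selected) == [8, 9]

    def test_all_equal_counts_select_nothing(self):
        assert driver_screen.percentile_select({"a": 3, "b": 3, "c": 3}, 0) == []

    def test_zero_percentile_strictly_above_minimum(self):
        selected = driver_screen.percentile_select(self.WORKED, 0)
        assert sorted(self.WORKED[g] for g in selected) == [2, 2, 3, 3, 3, 3, 8, 9]

    @pytest.mark.parametrize("x", [-1, 100, 120])
    def test_out_of_range_percentile_rejected(self, x):
        with pytest.raises(ValueError):
            driver_screen.percentile_select(self.WORKED, x)

    @pytest.mark.parametrize("x", [50, 70, 90])
    def test_matches_sort_based_recomputation(self, x):
        rng = np.random.default_rng(14)
        counts = {f"g{i}": int(c) for i, c in enumerate(rng.integers(0, 40, size=1000))}
        got = set(driver_screen.percentile_select(counts, x))
        values = np.sort(np.array(list(counts.values()), dtype=float))
        rank = (len(values) - 1) * x / 100.0
        lo = int(np.floor(rank))
        frac = rank - lo
        cut = values[lo] * (1 - frac) + values[min(lo + 1, len(values) - 1)] * frac
        want = {g for g, c in counts.items() if c > cut}
        assert got == want


class TestCancerFraction:
    def test_selection_inside_set_is_one(self):
        assert driver_screen.cancer_fraction({"G1"}, CANCER)["union"] == 1.0

    def test_disjoint_selection_is_zero(self):
        assert driver_screen.cancer_fraction({"ZZ"}, CANCER)["union"] == 0.0

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            driver_screen.cancer_fraction(set(), CANCER)

    def test_group_fractions_non_decreasing_on_cohort(self, default_cohort):
        syn = [
            v
            for v in default_cohort.variants
            if v.category == "somatic_cancer" and v.consequence == "synonymous"
        ]
        table = driver_screen.classify_gene_groups(syn, default_cohort.truth.thresholds)
        fractions = []
        for group in (1, 2, 3, 4):
            genes = table.loc[table["group"] >= group if group > 1 else table["group"] == 1, "gene"]
            if len(genes):
                fractions.append(
                    driver_screen.cancer_fraction(set(genes), default_cohort.gene_sets)["union"]
                )
        assert all(a <= b for a, b in zip(fractions, fractions[1:]))


class TestExcludePopulationObserved:
    def test_observed_variant_removed(self):
        assert driver_screen.exclude_population_observed([variant(pop_freq=0.001)]) == []

    def test_zero_frequency_kept(self):
        assert len(driver_screen.exclude_population_observed([variant(pop_freq=0.0)])) == 1

    def test_missing_frequency_kept(self):
        assert len(driver_screen.exclude_population_observed([variant()])) == 1

    def test_driver_median_still_highest_after_exclusion(self, small_cohort):
        kept = driver_screen.exclude_population_observed(small_cohort.variants)
        medians = {}
        for cat in ("putative_driver", "somatic_normal", "somatic_cancer"):
            vals = [
                v.scores["effect_score"]
                for v in kept
                if v.category == cat and "effect_score" in v.scores
            ]
            medians[cat] = float(np.median(vals))
        assert medians["putative_driver"] > medians["somatic_normal"]
        assert medians["putative_driver"] > medians["somatic_cancer"]


class TestMedianStrictness:
    def test_half_of_distinct_reference_fails_each_strict_filter(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            n = int(rng.integers(3, 40))
            effects = rng.permutation(np.linspace(0.01, 0.99, n))
            gerps = rng.permutation(np.linspace(-3, 6, n))
            ref = [
                variant(pos=i + 1, effect=float(e), gerp=float(g))
                for i, (e, g) in enumerate(zip(effects, gerps))
            ]
            tau = driver_screen.derive_thresholds(ref)
            fail_eff = sum(1 for v in ref if not v.scores["effect_score"] > tau.tau_effect)
            fail_cons = sum(1 for v in ref if not v.scores["gerp"] > tau.tau_cons)
            assert fail_eff >= -(-n // 2)
            assert fail_cons >= -(-n // 2)
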