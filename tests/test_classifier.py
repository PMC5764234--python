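"""Phenotype calls, rescue scan semantics, gap decision tree, ledger."""

import numpy as np
import pandas as pd
import pytest

from auxofill import classify as cl
from auxofill import gaps as gp


def exp_row(exp_id, media_class="defined", supplements="", group=None, t0="t0"):
    return {"exp_id": exp_id, "media_class": media_class,
            "supplements": supplements, "carbon_source": "glucose",
            "nitrogen_source": "ammonia",
            "replicate_group": group or exp_id, "time0_id": t0,
            "generations": 6.0}


@pytest.fixture
def exps():
    return pd.DataFrame([
        exp_row("min1", group="min"), exp_row("min2", group="min"),
        exp_row("plus_ser1", supplements="ser:1", group="plus_ser"),
        exp_row("plus_ser2", supplements="ser:1", group="plus_ser"),
        exp_row("rich1", media_class="rich", group="rich"),
        exp_row("cas1", supplements="casamino_acids:5", group="cas"),
    ])


def fit_matrix(rows):
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=["min1", "min2", "plus_ser1",
                                           "plus_ser2", "rich1", "cas1"])


class TestPhenotypeCall:
    def test_strong_defect_rescued_by_amino_acids_is_auxotrophic(self, exps):
        fit = fit_matrix({"g1": [-5.1, -4.8, -0.1, 0.2, 0.05, -0.2]})
        call = cl.phenotype_call("g1", fit, exps, essentials=set())
        assert call.label == "auxotrophic"
        assert call.median_defined == pytest.approx(-4.95)

    def test_everything_near_zero_is_no_phenotype(self, exps):
        fit = fit_matrix({"g1": [-0.4, 0.3, -0.2, 0.1, 0.45, -0.3]})
        assert cl.phenotype_call("g1", fit, exps, set()).label == "no_phenotype"

    def test_defect_without_rescue_is_no_phenotype(self, exps):
        # sick everywhere, including rich media: not an auxotrophy pattern
        fit = fit_matrix({"g1": [-4.0, -3.5, -3.8, -4.2, -3.0, -3.3]})
        assert cl.phenotype_call("g1", fit, exps, set()).label == "no_phenotype"

    def test_essential_set_takes_precedence(self, exps):
        fit = fit_matrix({"g1": [np.nan] * 6})
        assert cl.phenotype_call("g1", fit, exps, {"g1"}).label == "essential"
        assert cl.phenotype_call("g2", fit, exps, {"g2"}).label == "essential"

    def test_missing_most_defined_data_is_no_data(self, exps):
        fit = fit_matrix({"g1": [np.nan, -5.0, 0.0, 0.0, 0.0, 0.0]})
        assert cl.phenotype_call("g1", fit, exps, set()).label == "no_data"

    def test_defect_in_minority_of_defined_media_is_not_auxotrophic(self):
        exps4 = pd.DataFrame([exp_row(f"min{i}", group=f"m{i}") for i in range(4)]
                             + [exp_row("rich1", media_class="rich")])
        fit = pd.DataFrame({"min0": [-4.0], "min1": [-0.1], "min2": [0.0],
                            "min3": [0.1], "rich1": [0.0]}, index=["g1"])
        assert cl.phenotype_call("g1", fit, exps4, set()).label == "no_phenotype"

    def test_no_defined_experiments_is_config_error(self):
        exps = pd.DataFrame([exp_row("rich1", media_class="rich")])
        fit = pd.DataFrame({"rich1": [0.0]}, index=["g1"])
        with pytest.raises(ValueError):
            cl.phenotype_call("g1", fit, exps, set())


class TestRescueScan:
    def scan(self, minimal, supplemented, **kwargs):
        exps = pd.DataFrame([
            exp_row("min1", group="min"),
            exp_row("plus1", supplements="ser:1", group="plus"),
        ])
        fit = pd.DataFrame({"min1": [minimal], "plus1": [supplemented]},
                           index=["g1"])
        res = cl.rescue_scan(fit, exps, "ser", **kwargs)
        return res[0]

    def test_clear_rescue(self):
        assert self.scan(-3.5, -0.2).rescued

    def test_supplement_must_restore_fitness(self):
        assert not self.scan(-3.5, -2.5).rescued

    def test_boundaries_are_strict(self):
        # "under -2" and "above -1" are strict inequalities
        assert not self.scan(-2.0, 0.0).rescued
        assert not self.scan(-3.0, -1.0).rescued
        assert self.scan(-2.0000001, -0.9999999).rescued

    def test_relaxing_f_high_never_removes_rescues(self):
        rng = np.random.default_rng(5)
        exps = pd.DataFrame([
            exp_row("min1", group="min"),
            exp_row("plus1", supplements="ser:1", group="plus"),
        ])
        fit = pd.DataFrame({"min1": rng.normal(-2, 1.5, 50),
                            "plus1": rng.normal(-1, 0.8, 50)},
                           index=[f"g{i}" for i in range(50)])
        strict = {r.gene_id for r in cl.rescue_scan(fit, exps, "ser",
                                                    f_high=-0.5) if r.rescued}
        loose = {r.gene_id for r in cl.rescue_scan(fit, exps, "ser",
                                                   f_high=-1.5) if r.rescued}
        assert strict <= loose

    def test_replicates_averaged_before_thresholding(self, exps):
        # reps (-2.5, -1.6) average to -2.05 (< -2, rescue possible), while
        # (-2.5, -1.4) average to -1.95 and fail the minimal-media criterion
        fit = fit_matrix({"g1": [-2.5, -1.6, -0.1, -0.3, 0.0, 0.0],
                          "g2": [-2.5, -1.4, -0.1, -0.3, 0.0, 0.0]})
        res = {r.gene_id: r for r in cl.rescue_scan(fit, exps, "ser")}
        assert res["g1"].rescued
        assert not res["g2"].rescued

    def test_sorted_by_rescue_strength(self, exps):
        fit = fit_matrix({"weak": [-2.5, -2.5, -0.9, -0.9, 0, 0],
                          "strong": [-5.0, -5.0, 0.0, 0.0, 0, 0]})
        res = cl.rescue_scan(fit, exps, "ser")
        assert [r.gene_id for r in res] == ["strong", "weak"]

    def test_unknown_compound_rejected(self, exps):
        fit = fit_matrix({"g1": [0] * 6})
        with pytest.raises(ValueError):
            cl.rescue_scan(fit, exps, "trp")


def make_call(gene, label):
    return cl.PhenotypeCall(gene, label, -4.0 if label == "auxotrophic" else 0.0,
                            0.0, 4, 2)


class TestClassifyGap:
    def db(self):
        steps = pd.DataFrame([
            {"amino_acid": "ser", "variant_id": "v1", "step_index": i + 1,
             "reaction_id": r} for i, r in enumerate(["R1", "R2", "R3"])])
        reactions = pd.DataFrame({"reaction_id": ["R1", "R2", "R3"],
                                  "name": ["", "", ""],
                                  "is_transaminase": [False, False, False]})
        return gp.PathwayDB(steps, reactions)

    def annotations(self, entries):
        return pd.DataFrame(entries,
                            columns=["gene_id", "resource_id", "reaction_id"])

    def classify(self, gap, calls, rescue=(), annotations=()):
        return cl.classify_gap(gap, {c.gene_id: c for c in calls},
                               {"ser": list(rescue)},
                               self.annotations(list(annotations)), self.db())

    def test_clear_candidate_with_auxotrophic_phenotype(self):
        gap = gp.GapRecord("org", "ser", "R1", "v1", candidates=[("gA", 3)])
        assert self.classify(gap, [make_call("gA", "auxotrophic")]) \
            .classification == "clear_auxotrophic"

    def test_clear_candidate_essential(self):
        gap = gp.GapRecord("org", "ser", "R1", "v1", candidates=[("gA", 2)])
        assert self.classify(gap, [make_call("gA", "essential")]) \
            .classification == "clear_essential"

    def test_clear_candidate_without_coverage(self):
        gap = gp.GapRecord("org", "ser", "R1", "v1", candidates=[("gA", 2)])
        assert self.classify(gap, [make_call("gA", "no_data")]) \
            .classification == "clear_nodata"

    def test_multiple_clear_candidates_without_phenotype(self):
        gap = gp.GapRecord("org", "ser", "R1", "v1",
                           candidates=[("gA", 3), ("gB", 2)])
        got = self.classify(gap, [make_call("gA", "no_phenotype"),
                                  make_call("gB", "no_phenotype")])
        assert got.classification == "clear_multiple"

    def test_multiple_candidates_defer_to_the_one_with_phenotype(self):
        gap = gp.GapRecord("org", "ser", "R1", "v1",
                           candidates=[("gA", 3), ("gB", 2)])
        got = self.classify(gap, [make_call("gA", "no_phenotype"),
                                  make_call("gB", "auxotrophic")])
        assert got.classification == "clear_auxotrophic"

    def test_single_candidate_no_phenotype_with_backup_is_redundant(self):
        gap = gp.GapRecord("org", "ser", "R1", "v1", candidates=[("gA", 2),
                                                                 ("gB", 1)])
        got = self.classify(gap, [make_call("gA", "no_phenotype")],
                            annotations=[("gB", "res1", "R1")])
        assert got.classification == "clear_redundant"

    def test_single_candidate_no_phenotype_alone_is_other(self):
        gap = gp.GapRecord("org", "ser", "R1", "v1", candidates=[("gA", 2)])
        got = self.classify(gap, [make_call("gA", "no_phenotype")])
        assert got.classification == "clear_other"

    def test_genuine_gap_filled_by_rescued_unassigned_gene(self):
        gap = gp.GapRecord("org", "ser", "R3", "v1")
        rescue = [cl.RescueResult("gNew", "ser", -4.0, -0.1, True),
                  cl.RescueResult("gR1", "ser", -3.5, -0.2, True)]
        # gR1 is annotated to another step of the same pathway: not eligible
        got = self.classify(gap, [], rescue=rescue,
                            annotations=[("gR1", "res1", "R1")])
        assert got.classification == "genuine_filled"
        assert got.filled_by == "gNew"

    def test_genuine_gap_without_rescue_stays_unfilled(self):
        gap = gp.GapRecord("org", "ser", "R3", "v1")
        assert self.classify(gap, []).classification == "genuine_unfilled"

    def test_curated_flags_are_preserved(self):
        gap = gp.GapRecord("org", "ser", "R1", "v1", candidates=[("gA", 3)],
                           classification="transaminase")
        assert self.classify(gap, [make_call("gA", "auxotrophic")]) \
            .classification == "transaminase"


class TestLedger:
    def test_cases_sum_to_record_count(self, classified_gaps):
        summary = cl.summarize_ledger(classified_gaps)
        assert summary["cases"].sum() == len(classified_gaps)

    def test_unclassified_record_is_an_error(self):
        with pytest.raises(ValueError, match="PRX"):
            cl.summarize_ledger([gp.GapRecord("org", "his", "PRX", "v1")])

    def test_empty_ledger(self):
        assert cl.summarize_ledger([]).empty
        grid = cl.ledger_grid([], organisms=["org"])
        assert (grid == "").all().all()

    def test_grid_counts_repeated_codes(self):
        gaps = [gp.GapRecord("org", "his", f"R{i}", "v1",
                             classification="clear_auxotrophic")
                for i in range(2)]
        gaps.append(gp.GapRecord("org", "his", "R9", "v1",
                                 classification="transaminase"))
        grid = cl.ledger_grid(gaps, organisms=["org"], amino_acids=["his", "ser"])
        assert grid.loc["org", "his"] == "c2t"
        assert grid.loc["org", "ser"] == ""

    def test_reference_ledger_round_trips(self):
        reference = cl.load_reference_ledger()
        rebuilt = cl.summarize_ledger(cl.expand_summary(reference))
        pd.testing.assert_frame_equal(rebuilt, reference)

    def test_planted_world_summary_matches_truth(self, world, classified_gaps):
        summary = cl.summarize_ledger(classified_gaps)
        as_dict = {(r.group, r.subgroup): r.cases for r in summary.itertuples()}
        # one genuine gap (hidden everywhere) and one clear auxotrophic
        # candidate (hidden from the baseline only) were planted
        assert as_dict == {("Genuine gap", "filled (this study)"): 1,
                           ("Clear candidate", "auxotrophic"): 1}

    def test_planted_gap_filled_by_the_planted_gene(self, world, classified_gaps):
        truth = world.truth.set_index("gene_id")
        expected = truth.index[truth["role"] == "PRAMP-CH"][0]
        gap = [g for g in classified_gaps if g.reaction_id == "PRAMP-CH"][0]
        assert gap.classification == "genuine_filled"
        assert gap.filled_by == expected
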