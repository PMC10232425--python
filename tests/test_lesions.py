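import math
from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from hedscape.lesions import (
    HlaLesion,
    LesionSummary,
    LesionTableError,
    MyeloidMutation,
    comutation_enrichment,
    dli_response_crosstab,
    early_late_split,
    read_lesion_table,
    tabulate,
)
from hedscape.hla import parse_allele
from hedscape.synthetic import (
    fixture_dli_table,
    fixture_lesion_tables,
    fixture_myeloid_table,
)


@pytest.fixture(scope="module")
def fixture_f3():
    return fixture_lesion_tables()


def lesion(pid, tp="post_hct_relapse", allele="A*01:01", cat="missense"):
    return HlaLesion(pid, tp, parse_allele(allele), cat)


class TestReadLesionTable:
    def test_toy_round_trip(self, tmp_path):
        path = tmp_path / "les.tsv"
        path.write_text(
            "patient_id\ttimepoint\tallele\tcategory\tvaf\n"
            "P1\tdiagnosis\tA*02:01\tmissense\t0.3\n"
            "P2\tpost_hct_relapse\tDQB1*03:01\tloss\t\n"
            "P3\tpost_chemo_relapse\tC*07:01\tUTR\t0.1\n"
        )
        records = read_lesion_table(path)
        assert len(records) == 3
        assert records[1].vaf is None and records[0].vaf == 0.3

    def test_unknown_category_names_row(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "patient_id\ttimepoint\tallele\tcategory\n"
            "P1\tdiagnosis\tA*02:01\tpromoter\n"
        )
        with pytest.raises(LesionTableError, match="row 2.*promoter"):
            read_lesion_table(path)

    def test_unknown_timepoint_rejected(self):
        with pytest.raises(LesionTableError, match="timepoint"):
            lesion("P1", tp="relapse")

    def test_vaf_out_of_range(self):
        with pytest.raises(LesionTableError, match="VAF"):
            HlaLesion("P1", "diagnosis", parse_allele("A*01:01"), "missense", vaf=1.2)


class TestTabulate:
    def test_fixture_timepoint_marginals(self, fixture_f3):
        lesions, assayed = fixture_f3
        by_tp = {s.group: s for s in tabulate(lesions, assayed, "timepoint")}
        assert (by_tp["diagnosis"].numerator, by_tp["diagnosis"].denominator) == (9, 40)
        assert (by_tp["post_chemo_relapse"].numerator, by_tp["post_chemo_relapse"].denominator) == (0, 9)
        assert (by_tp["post_hct_relapse"].numerator, by_tp["post_hct_relapse"].denominator) == (17, 45)
        assert by_tp["post_chemo_relapse"].percent == 0
        # 26 lesion-positive patient-timepoints across diagnosis + post-HCT
        assert by_tp["diagnosis"].numerator + by_tp["post_hct_relapse"].numerator == 26

    def test_fixture_donor_type_frequencies(self, fixture_f3):
        lesions, assayed = fixture_f3
        post = assayed[assayed.timepoint == "post_hct_relapse"]
        post_lesions = [l for l in lesions if l.timepoint == "post_hct_relapse"]
        by_donor = {s.group: s for s in tabulate(post_lesions, post, "donor_type")}
        assert (by_donor["MRD"].numerator, by_donor["MRD"].denominator, by_donor["MRD"].percent) == (10, 20, 50)
        assert (by_donor["Haplo"].numerator, by_donor["Haplo"].denominator, by_donor["Haplo"].percent) == (2, 8, 25)
        assert (by_donor["MUD"].numerator, by_donor["MUD"].denominator, by_donor["MUD"].percent) == (5, 17, 29)
        # donor-type numerators partition the overall post-HCT numerator
        assert sum(s.numerator for s in by_donor.values()) == 17

    def test_patient_level_collapse(self):
        assayed = pd.DataFrame(
            [{"patient_id": "P1", "timepoint": "post_hct_relapse"},
             {"patient_id": "P2", "timepoint": "post_hct_relapse"}]
        )
        lesions = [lesion("P1"), lesion("P1", allele="B*01:01", cat="loss"),
                   lesion("P1", allele="C*01:01", cat="nonsense")]
        (s,) = tabulate(lesions, assayed, "timepoint")
        assert s.numerator == 1 and s.denominator == 2
        assert s.n_mutation_lesions == 2 and s.n_loss_lesions == 1

    def test_row_order_and_duplication_invariance(self, fixture_f3):
        lesions, assayed = fixture_f3
        shuffled = list(lesions)[::-1]
        base = tabulate(lesions, assayed, "timepoint")
        reordered = tabulate(shuffled, assayed, "timepoint")
        duplicated = tabulate(list(lesions) + list(lesions), assayed, "timepoint")
        for a, b, c in zip(base, reordered, duplicated):
            assert (a.group, a.numerator, a.denominator) == \
                   (b.group, b.numerator, b.denominator) == \
                   (c.group, c.numerator, c.denominator)

    def test_unassayed_lesion_is_error(self, fixture_f3):
        _, assayed = fixture_f3
        with pytest.raises(LesionTableError, match="P99"):
            tabulate([lesion("P99")], assayed, "timepoint")

    def test_percent_rounding_half_away_from_zero(self):
        assert LesionSummary("g", 1, 8, 0, 0).percent == 13  # 12.5 -> 13
        assert LesionSummary("g", 5, 17, 0, 0).percent == 29
        assert LesionSummary("g", 0, 0, 0, 0).percent == 0


class TestEarlyLateSplit:
    def test_fixture_split(self, fixture_f3):
        lesions, assayed = fixture_f3
        early, late = early_late_split(lesions, assayed)
        assert (early.numerator, early.denominator, early.percent) == (4, 14, 29)
        assert (late.numerator, late.denominator, late.percent) == (13, 31, 42)
        assert late.percent > early.percent

    def test_exactly_six_months_is_early(self):
        assayed = pd.DataFrame(
            [{"patient_id": "P1", "timepoint": "post_hct_relapse",
              "relapse_time_months": 6.0},
             {"patient_id": "P2", "timepoint": "post_hct_relapse",
              "relapse_time_months": 6.01}]
        )
        early, late = early_late_split([lesion("P1")], assayed)
        assert early.denominator == 1 and early.numerator == 1
        assert late.denominator == 1 and late.numerator == 0

    def test_no_late_relapses_flags_empty_summary(self):
        assayed = pd.DataFrame(
            [{"patient_id": "P1", "timepoint": "post_hct_relapse",
              "relapse_time_months": 1.0}]
        )
        early, late = early_late_split([], assayed)
        assert late.empty and late.percent == 0
        assert not early.empty

    def test_missing_time_is_error(self):
        assayed = pd.DataFrame(
            [{"patient_id": "P1", "timepoint": "post_hct_relapse",
              "relapse_time_months": np.nan}]
        )
        with pytest.raises(LesionTableError, match="P1"):
            early_late_split([], assayed)


def fisher_two_sided_enumeration(a, b, c, d):
    """Exhaustive hypergeometric enumeration over tables with fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def hyper(k):
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
        )

    p_obs = hyper(a)
    return sum(
        hyper(k)
        for k in range(max(0, c1 - r2), min(r1, c1) + 1)
        if hyper(k) <= p_obs * (1 + 1e-9)
    )


def build_enrichment_inputs(a, b, c, d, gene="RUNX1"):
    """Patients realizing the 2x2 (altered x mutated) table (a, b, c, d)."""
    tp = "post_hct_relapse"
    patients = [f"Q{i:02d}" for i in range(a + b + c + d)]
    assayed = pd.DataFrame({"patient_id": patients, "timepoint": tp})
    altered = patients[: a + b]
    mutated = patients[:a] + patients[a + b: a + b + c]
    lesions = [lesion(p) for p in altered]
    myeloid = [MyeloidMutation(p, tp, gene) for p in mutated]
    return lesions, myeloid, assayed


class TestComutationEnrichment:
    @pytest.mark.parametrize("table", [(3, 1, 1, 3), (5, 2, 1, 6), (2, 6, 3, 4), (1, 4, 4, 1)])
    def test_fisher_matches_exhaustive_enumeration(self, table):
        lesions, myeloid, assayed = build_enrichment_inputs(*table)
        out = comutation_enrichment(lesions, myeloid, assayed)
        assert out.loc["RUNX1", "p"] == pytest.approx(
            fisher_two_sided_enumeration(*table), rel=1e-9
        )

    def test_degenerate_gene_flagged_not_dropped(self):
        lesions, myeloid, assayed = build_enrichment_inputs(2, 2, 2, 2)
        with pytest.warns(UserWarning, match="degenerate"):
            out = comutation_enrichment(
                lesions, myeloid, assayed, genes=["RUNX1", "GHOST"]
            )
        assert out.loc["GHOST", "degenerate"]
        assert out.loc["GHOST", "odds_ratio"] == 1.0
        assert out.loc["GHOST", "p"] == 1.0

    def test_fixture_enrichment_ranks_configured_genes(self):
        lesions, assayed = fixture_lesion_tables()
        out = comutation_enrichment(lesions, fixture_myeloid_table(), assayed)
        assert {"RUNX1", "DNMT3A", "EZH2", "EP300"} <= set(out.index)
        assert (out["q"] >= out["p"] - 1e-12).all()
        # enriched genes carry smaller p than the background genes
        assert out.loc["RUNX1", "p"] < out.loc["TP53", "p"]

    def test_needs_both_strata(self):
        lesions, myeloid, assayed = build_enrichment_inputs(2, 2, 2, 2)
        with pytest.raises(LesionTableError, match="wild"):
            comutation_enrichment(
                lesions + [lesion(p) for p in assayed["patient_id"]], myeloid, assayed
            )


def test_dli_crosstab_fixture():
    lesions, _ = fixture_lesion_tables()
    table = dli_response_crosstab(
        [l for l in lesions if l.timepoint == "post_hct_relapse"],
        fixture_dli_table(),
    )
    assert table.loc["exonic_or_loss", "no_response"] == 6
    assert table.loc["utr_or_intronic", "no_response"] == 3
    assert table.loc["none", "complete_response"] == 5
    assert "complete_response" not in table.columns or \
        table.get("complete_response", pd.Series()).get("exonic_or_loss", 0) == 0
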