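"""Score computation, missing-data policies, and the analytic oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fhprs.panel import ApoeDiplotypeWeights, Group, ScorePanel, ScoreVariant
from fhprs.scoring import (
    ScoringError,
    compute_prs,
    expected_score,
    read_score_table,
    score_bounds,
    score_variance_hwe,
    scores_frame,
    write_score_table,
)

from _util import DIPLO_GENOTYPES, make_genotypes, uniform_cohort


class TestWorkedExtremes:
    """Hand-summed extreme scores from the published weight table."""

    @pytest.mark.parametrize(
        "dosage, diplotype, size, expected",
        [
            (2, "E4E4", 12, 65.22),   # 2 x 28.75 + 7.72
            (2, "E4E4", 6, 46.60),    # 2 x (5.65+4.05+2.75+6.99) + 7.72
            (0, "E2E2", 12, -34.75),  # only the diplotype term survives
            (0, "E2E2", 6, -34.75),
            (1, "E3E3", 12, 28.75),   # the sum of the ten weights
        ],
    )
    def test_extremes(self, panel, dosage, diplotype, size, expected):
        cg = uniform_cohort(panel, dosage, diplotype)
        [res] = compute_prs(cg, panel, panel_size=size)
        value = res.prs12 if size == 12 else res.prs6
        assert value == pytest.approx(expected, abs=1e-9)
        assert res.n_missing == 0

    def test_bounds_match_extremes(self, panel):
        assert score_bounds(panel, 12) == (pytest.approx(-34.75), pytest.approx(65.22))
        assert score_bounds(panel, 6) == (pytest.approx(-34.75), pytest.approx(46.60))


def _random_cohort(panel, n, seed):
    rng = np.random.default_rng(seed)
    rows = [rng.integers(0, 3, size=10).tolist() for _ in range(n)]
    diplos = rng.choice(list(DIPLO_GENOTYPES), size=n)
    return make_genotypes(panel, rows, [DIPLO_GENOTYPES[d] for d in diplos])


def test_linearity_prs12_minus_long_only_terms_is_prs6(panel):
    cg = _random_cohort(panel, 50, seed=5)
    results = compute_prs(cg, panel, panel_size="both")
    long_only = [v for v in panel.snp_variants if not v.in_6snp]
    for r in results:
        extra = sum(v.weight * cg.dosage.at[r.subject_id, v.rsid] for v in long_only)
        assert r.prs12 - extra == pytest.approx(r.prs6, abs=1e-9)


def test_scores_within_bounds(panel):
    cg = _random_cohort(panel, 200, seed=11)
    frame = scores_frame(compute_prs(cg, panel))
    lo12, hi12 = score_bounds(panel, 12)
    lo6, hi6 = score_bounds(panel, 6)
    assert frame.prs12.between(lo12 - 1e-9, hi12 + 1e-9).all()
    assert frame.prs6.between(lo6 - 1e-9, hi6 + 1e-9).all()


@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    dosages=st.lists(st.integers(0, 2), min_size=10, max_size=10),
    bump=st.integers(0, 9),
    diplo=st.sampled_from(sorted(DIPLO_GENOTYPES)),
)
def test_monotonicity_one_extra_risk_allele_adds_its_weight(panel, dosages, bump, diplo):
    if dosages[bump] == 2:
        dosages = list(dosages)
        dosages[bump] = 1
    bumped = list(dosages)
    bumped[bump] += 1
    cg = make_genotypes(panel, [dosages, bumped],
                        [DIPLO_GENOTYPES[diplo], DIPLO_GENOTYPES[diplo]])
    a, b = compute_prs(cg, panel, panel_size=12)
    weight = panel.snp_variants[bump].weight
    assert b.prs12 - a.prs12 == pytest.approx(weight, abs=1e-9)


class TestMissingPolicies:
    def _cohort_with_hole(self, panel):
        rows = [{v.rsid: 1.0 for v in panel.snp_variants} for _ in range(2)]
        del rows[1]["rs629301"]
        return make_genotypes(panel, rows,
                              [DIPLO_GENOTYPES["E3E3"], DIPLO_GENOTYPES["E3E3"]])

    def test_fail_lists_subject_and_variant(self, panel):
        with pytest.raises(ScoringError, match="rs629301"):
            compute_prs(self._cohort_with_hole(panel), panel, missing_policy="fail")

    def test_omit_contributes_zero_and_reports(self, panel):
        res = compute_prs(self._cohort_with_hole(panel), panel, missing_policy="omit")
        assert res[0].n_missing == 0 and res[1].n_missing == 1
        assert res[0].prs12 - res[1].prs12 == pytest.approx(5.65)  # the omitted weight

    def test_expected_impute_uses_group_frequency(self, panel):
        res = compute_prs(self._cohort_with_hole(panel), panel,
                          missing_policy="expected_impute", impute_group="CONTROL")
        f = panel.risk_allele_frequency("rs629301", "CONTROL")
        gap = res[0].prs12 - res[1].prs12
        assert gap == pytest.approx(5.65 * (1.0 - 2.0 * f), abs=1e-9)

    def test_expected_impute_requires_group(self, panel):
        with pytest.raises(ScoringError, match="impute_group"):
            compute_prs(self._cohort_with_hole(panel), panel,
                        missing_policy="expected_impute")

    def test_unknown_diplotype_fail_and_omit(self, panel):
        rows = [{v.rsid: 1.0 for v in panel.snp_variants}]
        cg = make_genotypes(panel, rows, [("TT", None)])
        with pytest.raises(ScoringError, match="APOE"):
            compute_prs(cg, panel, missing_policy="fail")
        [res] = compute_prs(cg, panel, missing_policy="omit")
        assert res.apoe_diplotype == "UNKNOWN"
        assert res.prs12 == pytest.approx(28.75)  # diplotype term contributes 0
        assert res.n_missing == 1


def _toy_panel(maf, risk_is_minor, weight, apoe_freqs):
    """A minimal panel (one weighted SNP + the APOE pair) for oracle checks."""
    groups = {g: maf for g in Group}
    snp = ScoreVariant("rs1", "GENE", "A", "G", weight, False, risk_is_minor, groups)
    apoe1 = ScoreVariant("rs429358", "APOE", "C", "T", None, False, True, groups)
    apoe2 = ScoreVariant("rs7412", "APOE", "T", "C", None, False, True, groups)
    weights = {"E2E2": -34.75, "E2E3": -15.45, "E2E4": -7.72,
               "E3E3": 0.0, "E3E4": 3.86, "E4E4": 7.72}
    return ScorePanel(
        variants=(snp, apoe1, apoe2),
        apoe=ApoeDiplotypeWeights(weights=weights,
                                  group_freq={g: dict(apoe_freqs) for g in Group}),
    )


def test_expected_score_degenerate_all_e2e2():
    freqs = {d: 0.0 for d in ("E2E3", "E2E4", "E3E3", "E3E4", "E4E4")}
    freqs["E2E2"] = 1.0
    toy = _toy_panel(maf=0.0, risk_is_minor=True, weight=3.0, apoe_freqs=freqs)
    assert expected_score(toy, "CONTROL", 12) == pytest.approx(-34.75)
    assert score_variance_hwe(toy, "CONTROL", 12) == pytest.approx(0.0)


def test_variance_single_snp_half_frequency():
    freqs = {d: 0.0 for d in ("E2E2", "E2E3", "E2E4", "E3E4", "E4E4")}
    freqs["E3E3"] = 1.0
    w = 4.2
    toy = _toy_panel(maf=0.5, risk_is_minor=True, weight=w, apoe_freqs=freqs)
    assert score_variance_hwe(toy, "CONTROL", 12) == pytest.approx(w * w / 2.0)


def test_expected_score_uses_printed_unnormalized_diplotype_freqs(panel):
    """The analytic mean adds the diplotype term with frequencies exactly as
    published, even where the printed vector does not sum to 1."""
    value = expected_score(panel, "FH_M_POS", 12)
    snp_part = sum(v.weight * 2 * v.risk_allele_frequency("FH_M_POS")
                   for v in panel.weighted_variants(12))
    printed = panel.apoe.frequencies("FH_M_POS", normalized=False)
    apoe_part = sum(printed[d] * panel.apoe.weights[d] for d in printed)
    assert value == pytest.approx(snp_part + apoe_part, abs=1e-12)
    assert sum(printed.values()) < 0.95  # the printed vector really is short of 1


def test_score_table_round_trip(tmp_path, panel):
    cg = _random_cohort(panel, 8, seed=2)
    results = compute_prs(cg, panel)
    path = tmp_path / "scores.tsv"
    write_score_table(results, path)
    frame = read_score_table(path)
    original = scores_frame(results)
    assert np.allclose(frame["prs12"], original["prs12"].astype(float).round(2))
    assert list(frame["apoe_diplotype"]) == list(original["apoe_diplotype"])
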