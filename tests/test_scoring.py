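"""Triage scoring: point banding, comorbidity allotment, priority groups,
tiebreak cascade and the allocation simulator."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from csctriage.scoring import (
    ComorbidityCatalog,
    Ordering,
    TiebreakProfile,
    Tier,
    TriageResult,
    allocate,
    comorbidity_points,
    priority_group,
    priority_score,
    score_table,
    sofa_only_group,
    sofa_points,
    tiebreak_compare,
    triage,
)


@pytest.fixture(scope="module")
def catalog():
    return ComorbidityCatalog.default()


# --- SOFA points banding ---------------------------------------------------


@pytest.mark.parametrize(
    "score,points",
    [(0, 1), (4, 1), (5, 1), (6, 2), (8, 2), (9, 3), (10, 3), (11, 3), (12, 4), (24, 4)],
)
def test_sofa_points_bands(score, points):
    assert sofa_points(score) == points


def test_sofa_points_full_range_matches_lookup():
    lookup = lambda s: 1 if s < 6 else 2 if s < 9 else 3 if s < 12 else 4
    assert [sofa_points(s) for s in range(25)] == [lookup(s) for s in range(25)]


@pytest.mark.parametrize("bad", [-1, 25])
def test_sofa_points_rejects_out_of_range(bad):
    with pytest.raises(ValueError):
        sofa_points(bad)


# --- comorbidity points ----------------------------------------------------


def test_default_catalog_has_six_five_year_and_nine_one_year(catalog):
    tiers = list(catalog.tiers.values())
    assert tiers.count(Tier.FIVE_YEAR) == 6
    assert tiers.count(Tier.ONE_YEAR) == 9


@pytest.mark.parametrize(
    "codes,points",
    [
        (set(), 0),
        ({"moderate_dementia"}, 2),
        ({"severe_dementia"}, 4),
        # single allotment: never summed across comorbidities
        ({"moderate_dementia", "end_stage_kidney_disease", "metastatic_stage_iv_cancer"}, 4),
        ({"moderate_dementia", "moderate_lung_disease"}, 2),
    ],
)
def test_comorbidity_points_single_allotment(codes, points, catalog):
    assert comorbidity_points(codes, catalog) == points


def test_unknown_comorbidity_code_named_in_error(catalog):
    with pytest.raises(KeyError, match="gout"):
        comorbidity_points({"gout"}, catalog)


# --- priority score and groups ---------------------------------------------


def test_priority_score_is_exact_sum_and_surjective():
    seen = set()
    for sp, cp in itertools.product((1, 2, 3, 4), (0, 2, 4)):
        s = priority_score(sp, cp)
        assert s == sp + cp and 1 <= s <= 8
        seen.add(s)
    assert seen == set(range(1, 9))


def test_priority_group_default_mapping_matches_brute_force():
    brute = lambda s: 1 if s <= 3 else 2 if s <= 5 else 3
    assert [priority_group(s) for s in range(1, 9)] == [brute(s) for s in range(1, 9)]


def test_priority_group_is_configurable():
    gm = {1: (1, 2), 2: (3, 4), 3: (5, 8)}
    assert priority_group(3, gm) == 2
    assert priority_group(5, gm) == 3


@pytest.mark.parametrize("bad", [0, 9])
def test_priority_group_rejects_out_of_range(bad):
    with pytest.raises(ValueError):
        priority_group(bad)


def test_sofa_only_group_merges_points_3_and_4():
    assert [sofa_only_group(p) for p in (1, 2, 3, 4)] == [1, 2, 3, 3]


def test_adding_comorbidity_never_decreases_score(catalog):
    for sofa in range(25):
        none = triage(sofa, (), catalog)
        five = triage(sofa, ["moderate_dementia"], catalog)
        one = triage(sofa, ["severe_dementia"], catalog)
        assert none.priority_score <= five.priority_score <= one.priority_score


def test_relative_priority_can_move_both_ways(catalog):
    # sofa points 2, no comorbidity: full group 1 outranks SOFA-only group 2
    r = triage(6, (), catalog)
    assert r.sofa_points == 2 and r.priority_group == 1
    assert sofa_only_group(r.sofa_points) == 2
    # sofa points 1 with a 1-year comorbidity moves the other way
    r2 = triage(0, ["severe_dementia"], catalog)
    assert sofa_only_group(r2.sofa_points) == 1 and r2.priority_group == 2


# --- tiebreak cascade ------------------------------------------------------


def _entry(group, score, strc=False, age=50.0, essential=False):
    sp = min(score, 4) if score <= 4 else score - 4
    sp = max(1, min(4, sp))
    res = TriageResult(sp, score - sp, score, group)
    return res, TiebreakProfile(strc, age, essential)


def test_tiebreak_examples():
    a = _entry(1, 2)
    b = _entry(2, 2)
    assert tiebreak_compare(a, b) is Ordering.A_FIRST
    young = _entry(1, 3, age=40)
    old = _entry(1, 3, age=70)
    assert tiebreak_compare(young, old) is Ordering.A_FIRST
    assert tiebreak_compare(old, young) is Ordering.B_FIRST
    assert tiebreak_compare(young, young) is Ordering.TIE


def test_tiebreak_cascade_order():
    # short-term-recovery comorbidity outranks age; age outranks essential
    # function; essential function outranks raw score
    no_strc_old = _entry(2, 4, strc=False, age=80)
    strc_young = _entry(2, 4, strc=True, age=30)
    assert tiebreak_compare(no_strc_old, strc_young) is Ordering.A_FIRST
    young_plain = _entry(2, 4, age=30)
    old_essential = _entry(2, 4, age=80, essential=True)
    assert tiebreak_compare(young_plain, old_essential) is Ordering.A_FIRST
    essential_high = _entry(2, 5, essential=True)
    plain_low = _entry(2, 4, essential=False)
    assert tiebreak_compare(essential_high, plain_low) is Ordering.A_FIRST


def test_tiebreak_is_strict_weak_ordering():
    grid = [
        _entry(g, s, strc, age, ess)
        for g in (1, 2)
        for s in (2, 5)
        for strc in (False, True)
        for age in (40.0, 70.0)
        for ess in (False, True)
    ]
    for a, b in itertools.product(grid, repeat=2):
        ab, ba = tiebreak_compare(a, b), tiebreak_compare(b, a)
        # antisymmetry up to tie
        assert (ab, ba) in {
            (Ordering.A_FIRST, Ordering.B_FIRST),
            (Ordering.B_FIRST, Ordering.A_FIRST),
            (Ordering.TIE, Ordering.TIE),
        }
    for a, b, c in itertools.product(grid, repeat=3):
        if (
            tiebreak_compare(a, b) is Ordering.A_FIRST
            and tiebreak_compare(b, c) is Ordering.A_FIRST
        ):
            assert tiebreak_compare(a, c) is Ordering.A_FIRST


# --- allocation simulator --------------------------------------------------


def test_allocate_no_scarcity_allocates_everyone():
    cohort = [(f"p{i}", *_entry(1, 1 + i % 3)) for i in range(3)]
    assert set(allocate(cohort, 5, seed=0)) == {"p0", "p1", "p2"}


def test_allocate_seeded_lottery_is_reproducible():
    cohort = [("x", *_entry(1, 2, age=50)), ("y", *_entry(1, 2, age=50))]
    first = allocate(cohort, 1, seed=42)
    assert len(first) == 1
    for _ in range(5):
        assert allocate(cohort, 1, seed=42) == first
    other = {allocate(cohort, 1, seed=s)[0] for s in range(40)}
    assert other == {"x", "y"}  # the lottery is not degenerate


def test_allocate_distinct_scores_matches_sort_oracle():
    rng = np.random.default_rng(5)
    scores = rng.permutation(np.arange(1, 9))[:8]
    cohort = [(f"p{s}", *_entry(priority_group(int(s)), int(s))) for s in scores]
    got = allocate(cohort, 4, seed=0)
    want = [f"p{s}" for s in sorted(scores)[:4]]
    assert got == want


def test_allocate_rejects_negative_resources():
    with pytest.raises(ValueError):
        allocate([], -1, seed=0)


# --- vectorised table scoring ----------------------------------------------


def test_score_table_matches_scalar_triage(catalog):
    rng = np.random.default_rng(9)
    n = 60
    codes_pool = ["none", "moderate_dementia", "severe_dementia",
                  "moderate_dementia;metastatic_stage_iv_cancer"]
    patients = pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(n)],
            "comorbidities": rng.choice(codes_pool, n),
        }
    )
    days = pd.DataFrame(
        {
            "patient_id": rng.choice(patients["patient_id"], 150),
            "sofa_score": rng.integers(0, 25, 150).astype(float),
        }
    )
    out = score_table(days, patients, catalog)
    pmap = patients.set_index("patient_id")["comorbidities"]
    for _, row in out.iterrows():
        codes = pmap[row["patient_id"]]
        codes = [] if codes == "none" else codes.split(";")
        want = triage(int(row["sofa_score"]), codes, catalog)
        assert row["sofa_points"] == want.sofa_points
        assert row["comorbidity_points"] == want.comorbidity_points
        assert row["priority_score"] == want.priority_score
        assert row["priority_group"] == want.priority_group
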