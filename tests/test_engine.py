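"""Algorithm engine: parsing, joint-use constraints, evaluation, filters,
candidate enumeration."""

import itertools
from datetime import date

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from casefinder.atoms import (
    ATOM_LABELS,
    INDEPENDENT_ATOMS,
    JOINT_ONLY_ATOMS,
    AtomResult,
    compute_all_atoms,
)
from casefinder.engine import (
    AlgorithmSpec,
    And,
    CohortResult,
    Leaf,
    Or,
    apply_age_filter,
    apply_older_age_exclusion,
    builtin_algorithms,
    enumerate_candidates,
    evaluate,
    parse_algorithm,
    qualifying_dates,
)
from casefinder.pipeline import build_cohort

from conftest import WINDOW, brute_eval, make_tables, random_fixture


# ---------------------------------------------------------------------------
# parsing


@pytest.mark.parametrize(
    "text",
    [
        "DX OR R02 OR FEP OR EIP",
        "DX OR (CLUSTER AND HONOS)",
        "DX",
        "R18 AND EIP",
        "(R01 AND FEP) OR DX",
        "DX OR (CLUSTER AND HONOS) OR (R18 AND EIP)",
        "dx or r02",  # case-insensitive
    ],
)
def test_valid_expressions_parse(text):
    spec = parse_algorithm(text)
    assert spec.leaves() <= set(ATOM_LABELS)


@pytest.mark.parametrize(
    "text, match",
    [
        ("DX OR HONOS", "HONOS"),          # joint-only atom bare at top level
        ("HONOS", "HONOS"),
        ("CLUSTER OR DX", "CLUSTER"),
        ("R01 OR DX", "R01"),
        ("DX OR (HONOS OR CLUSTER)", "joint-only"),  # nested OR is still bare
        ("R18 AND DX", "R18"),             # R18 must be joined with EIP
        ("DX OR BANANA", "unknown atom"),
        ("DX OR", "unexpected end"),
        ("(DX", "unbalanced|unexpected end"),
        ("", "empty"),
        ("DX AND OR", "misplaced"),
    ],
)
def test_invalid_expressions_rejected_with_named_cause(text, match):
    with pytest.raises(ValueError, match=match):
        parse_algorithm(text)


def test_parse_is_canonical():
    a = parse_algorithm("FEP OR DX OR (HONOS AND CLUSTER)")
    b = parse_algorithm("DX OR (CLUSTER AND HONOS) OR FEP")
    assert a.expression == b.expression
    assert a.expression_text == b.expression_text


def test_builtin_algorithms_ship_the_four_printed_compositions():
    builtins = {s.id: s for s in builtin_algorithms()}
    assert len(builtins) == 4
    expected = {
        "A1": "DX OR R02 OR FEP OR EIP",
        "A5": "DX OR R02 OR FEP OR (CLUSTER AND HONOS)",
        "A6": "DX OR FEP OR EIP",
        "A7": "DX OR FEP OR EIP OR (CLUSTER AND HONOS)",
    }
    for alg_id, text in expected.items():
        assert builtins[alg_id].expression == parse_algorithm(text).expression


# ---------------------------------------------------------------------------
# evaluation


def _atoms_from_sets(sets: dict[str, set[str]]) -> dict[str, AtomResult]:
    return {
        a: AtomResult(a, WINDOW, frozenset(sets.get(a, set())),
                      {p: WINDOW.start for p in sets.get(a, set())})
        for a in ATOM_LABELS
    }


FIVE_PATIENT_SETS = {
    "DX": {"P1"}, "FEP": {"P2"}, "EIP": {"P3"},
    "CLUSTER": {"P4"}, "HONOS": {"P4"},
}


def test_evaluate_five_patient_fixture():
    """P1 primary F20 only, P2 FEP only, P3 EIP only, P4 cluster+HoNOS only,
    P5 nothing: A6 selects P1-P3 and A7 additionally P4."""
    atoms = _atoms_from_sets(FIVE_PATIENT_SETS)
    by_id = {s.id: s for s in builtin_algorithms()}
    assert evaluate(by_id["A6"], atoms, WINDOW).patients == {"P1", "P2", "P3"}
    assert evaluate(by_id["A7"], atoms, WINDOW).patients == {"P1", "P2", "P3", "P4"}


def test_evaluate_empty_atoms_gives_empty_cohort():
    atoms = _atoms_from_sets({})
    for spec in builtin_algorithms():
        assert evaluate(spec, atoms, WINDOW).count == 0


def test_evaluate_missing_atom_is_named():
    atoms = _atoms_from_sets(FIVE_PATIENT_SETS)
    del atoms["EIP"]
    with pytest.raises(KeyError, match="EIP"):
        evaluate(parse_algorithm("DX OR EIP"), atoms, WINDOW)


def test_evaluate_rejects_mismatched_window():
    from casefinder.model import AnalysisWindow

    other = AnalysisWindow("2017-2018", date(2017, 4, 1), date(2018, 4, 1))
    atoms = _atoms_from_sets(FIVE_PATIENT_SETS)
    with pytest.raises(ValueError, match="window"):
        evaluate(parse_algorithm("DX"), atoms, other)


# random expressions respecting the joint-use constraints
_independent = st.sampled_from(sorted(INDEPENDENT_ATOMS))
_composite = st.one_of(
    st.just(And((Leaf("CLUSTER"), Leaf("HONOS")))),
    st.just(And((Leaf("R01"), Leaf("FEP")))),
    st.just(And((Leaf("R18"), Leaf("EIP")))),
    st.just(And((Leaf("CLUSTER"), Leaf("HONOS"), Leaf("R01")))),
    st.just(And((Leaf("DX"), Leaf("HONOS")))),
)
_expression = st.tuples(
    st.lists(_independent, min_size=1, max_size=4, unique=True),
    st.lists(_composite, min_size=0, max_size=3, unique_by=str),
).map(lambda t: (
    Leaf(t[0][0]) if len(t[0]) == 1 and not t[1]
    else Or(tuple([Leaf(a) for a in t[0]] + list(t[1])))
))


@settings(derandomize=True, max_examples=60, deadline=None)
@given(expr=_expression, seed=st.integers(0, 2**16))
def test_evaluate_matches_per_patient_truth_table(expr, seed):
    rng = np.random.default_rng(seed)
    pids = [f"P{i}" for i in range(60)]
    sets = {
        a: set(rng.choice(pids, size=int(rng.integers(0, 30)), replace=False))
        for a in ATOM_LABELS
    }
    atoms = _atoms_from_sets(sets)
    spec = AlgorithmSpec(id="t", expression=expr)
    got = evaluate(spec, atoms, WINDOW).patients
    assert got == brute_eval(expr, pids, sets)


def test_or_monotonicity_and_and_containment():
    rng = np.random.default_rng(31)
    tables = random_fixture(rng, 300)
    atoms = compute_all_atoms(tables, WINDOW)
    by_id = {s.id: s for s in builtin_algorithms()}
    a1 = evaluate(by_id["A1"], atoms, WINDOW).patients
    a6 = evaluate(by_id["A6"], atoms, WINDOW).patients
    a7 = evaluate(by_id["A7"], atoms, WINDOW).patients
    assert a6 <= a1 and a6 <= a7
    ch = evaluate(parse_algorithm("CLUSTER AND HONOS"), atoms, WINDOW).patients
    assert ch <= atoms["CLUSTER"].patients and ch <= atoms["HONOS"].patients


# ---------------------------------------------------------------------------
# age filter


def _boundary_tables(ages, qual=date(2018, 6, 1)):
    """One patient per requested age, each with a code-02 referral on the
    exact birthday anniversary (so age at the qualifying date is exact)."""
    patients, referrals = [], []
    for a in ages:
        pid = f"AGE{a}"
        patients.append((pid, date(qual.year - a, qual.month, qual.day), "1"))
        referrals.append((pid, qual, "02"))
    return make_tables(patients=patients, referrals=referrals)


@pytest.mark.parametrize(
    "mode, kept",
    [
        ("incident", {14, 65}),          # 14-65 at diagnosis
        ("prevalent", {14, 65, 66, 105}),  # 14-105
    ],
)
def test_age_filter_boundaries(mode, kept):
    ages = [13, 14, 65, 66, 105, 106]
    tables = _boundary_tables(ages)
    atoms = compute_all_atoms(tables, WINDOW)
    spec = parse_algorithm("R02", id="r02", mode=mode)
    raw = evaluate(spec, atoms, WINDOW)
    qd = qualifying_dates(spec, atoms, raw)
    out = apply_age_filter(raw, tables.patients, mode, qd)
    assert out.patients == {f"AGE{a}" for a in kept}


def test_age_filter_matches_bruteforce_refilter():
    from casefinder.model import age_at

    rng = np.random.default_rng(3)
    tables = random_fixture(rng, 200)
    atoms = compute_all_atoms(tables, WINDOW)
    spec = parse_algorithm("DX OR R02", id="x", mode="incident")
    raw = evaluate(spec, atoms, WINDOW)
    qd = qualifying_dates(spec, atoms, raw)
    out = apply_age_filter(raw, tables.patients, "incident", qd)
    births = {
        str(r["patient_id"]): r["birth_date"].date()
        for _, r in tables.patients.iterrows()
    }
    expected = {
        p for p in raw.patients if 14 <= age_at(births[p], qd[p]) <= 65
    }
    assert out.patients == expected


def test_age_filter_requires_qualifying_date_and_mode():
    cohort = CohortResult("x", WINDOW, frozenset({"P1"}))
    tables = make_tables(patients=[("P1", date(1990, 1, 1), "1")])
    with pytest.raises(ValueError, match="qualifying date"):
        apply_age_filter(cohort, tables.patients, "incident", {})
    with pytest.raises(ValueError, match="mode"):
        apply_age_filter(cohort, tables.patients, "lifetime", {"P1": date(2018, 5, 1)})


def test_age_filter_is_idempotent():
    rng = np.random.default_rng(17)
    tables = random_fixture(rng, 150)
    atoms = compute_all_atoms(tables, WINDOW)
    spec = parse_algorithm("DX OR FEP", id="x", mode="prevalent")
    raw = evaluate(spec, atoms, WINDOW)
    qd = qualifying_dates(spec, atoms, raw)
    once = apply_age_filter(raw, tables.patients, "prevalent", qd)
    twice = apply_age_filter(once, tables.patients, "prevalent", qd)
    assert once.patients == twice.patients


# ---------------------------------------------------------------------------
# older-age (dementia / psychotic depression) exclusion


def _older_fixture(age, with_exclusion_code, code="F00.1"):
    qual = date(2018, 6, 1)
    patients = [("P1", date(qual.year - age, qual.month, qual.day), "1")]
    flags = [("P1", "FEP", qual)]
    diagnoses = []
    if with_exclusion_code:
        diagnoses = [("P1", date(2018, 7, 1), "ICD10", code, "secondary")]
    return make_tables(patients=patients, diagnoses=diagnoses, flags=flags)


@pytest.mark.parametrize("code", ["F00.1", "F03", "G30.9", "F32.3"])
def test_first_episode_case_aged_60_with_exclusion_code_is_removed(code):
    tables = _older_fixture(60, True, code)
    atoms = compute_all_atoms(tables, WINDOW)
    spec = parse_algorithm("FEP OR DX", id="x")
    cohort = build_cohort(spec, atoms, tables, WINDOW)
    assert cohort.patients == frozenset()


def test_first_episode_case_aged_60_without_exclusion_code_is_kept():
    tables = _older_fixture(60, False)
    atoms = compute_all_atoms(tables, WINDOW)
    cohort = build_cohort(parse_algorithm("FEP OR DX", id="x"), atoms, tables, WINDOW)
    assert cohort.patients == {"P1"}


def test_exclusion_only_bites_in_the_55_65_band():
    for age, kept in [(54, True), (55, False), (65, False), (66, True)]:
        tables = _older_fixture(age, True)
        atoms = compute_all_atoms(tables, WINDOW)
        cohort = build_cohort(parse_algorithm("FEP OR DX", id="x"),
                              atoms, tables, WINDOW)
        assert (cohort.patients == {"P1"}) is kept, age


def test_exclusion_scope_first_episode_vs_strict():
    """Default scope: a non-first-episode member (code-02 referral evidence)
    aged 60 with a dementia code stays; strict mode removes them too."""
    qual = date(2018, 6, 1)
    tables = make_tables(
        patients=[("P1", date(1958, 6, 1), "1")],
        referrals=[("P1", qual, "02")],
        diagnoses=[("P1", date(2018, 7, 1), "ICD10", "F03", "secondary")],
    )
    atoms = compute_all_atoms(tables, WINDOW)
    spec = parse_algorithm("DX OR R02", id="x")
    raw = evaluate(spec, atoms, WINDOW)
    qd = qualifying_dates(spec, atoms, raw)
    fe = atoms["FEP"].patients | atoms["R01"].patients
    default = apply_older_age_exclusion(
        raw, tables.patients, tables.diagnoses, window=WINDOW, qual_dates=qd,
        first_episode_members=fe)
    strict = apply_older_age_exclusion(
        raw, tables.patients, tables.diagnoses, window=WINDOW, qual_dates=qd,
        first_episode_members=fe, strict=True)
    assert default.patients == {"P1"}
    assert strict.patients == frozenset()


def test_exclusion_is_vacuous_without_55_65_patients():
    rng = np.random.default_rng(29)
    tables = random_fixture(rng, 100)
    # shift every birth date so nobody is 55-65 in the window
    tables.patients["birth_date"] = date(1990, 1, 1)
    import pandas as pd

    tables.patients["birth_date"] = pd.to_datetime(tables.patients["birth_date"])
    atoms = compute_all_atoms(tables, WINDOW)
    spec = parse_algorithm("DX OR FEP", id="x")
    raw = evaluate(spec, atoms, WINDOW)
    qd = qualifying_dates(spec, atoms, raw)
    out = apply_older_age_exclusion(
        raw, tables.patients, tables.diagnoses, window=WINDOW, qual_dates=qd,
        first_episode_members=atoms["FEP"].patients, strict=True)
    assert out.patients == raw.patients


# ---------------------------------------------------------------------------
# qualifying dates


def test_qualifying_date_is_min_over_or_and_max_over_and():
    d1, d2, d3 = date(2018, 5, 1), date(2018, 8, 1), date(2018, 11, 1)
    atoms = {
        a: AtomResult(a, WINDOW, frozenset(), {}) for a in ATOM_LABELS
    }
    atoms["DX"] = AtomResult("DX", WINDOW, frozenset({"P"}), {"P": d2})
    atoms["CLUSTER"] = AtomResult("CLUSTER", WINDOW, frozenset({"P"}), {"P": d1})
    atoms["HONOS"] = AtomResult("HONOS", WINDOW, frozenset({"P"}), {"P": d3})
    spec = parse_algorithm("DX OR (CLUSTER AND HONOS)", id="x")
    cohort = evaluate(spec, atoms, WINDOW)
    # AND branch completes at d3 (both parts needed); OR takes the earlier of
    # DX at d2 and the composite at d3
    assert qualifying_dates(spec, atoms, cohort)["P"] == d2


# ---------------------------------------------------------------------------
# enumeration


def test_enumeration_counts_small_cases():
    assert len(enumerate_candidates(["DX"], composites=())) == 1
    assert len(enumerate_candidates(["DX", "R02"], composites=())) == 3
    with pytest.raises(ValueError):
        enumerate_candidates([], composites=())


def test_enumeration_matches_powerset_oracle():
    """Default inventory: non-empty subsets of 4 independent atoms crossed
    with subsets of 3 joint composites, counted independently."""
    specs = enumerate_candidates()
    oracle = 0
    for r in range(1, 5):
        for _ in itertools.combinations(range(4), r):
            for k in range(4):
                oracle += len(list(itertools.combinations(range(3), k)))
    assert len(specs) == oracle == 120
    texts = [s.expression_text for s in specs]
    assert len(set(texts)) == len(texts)  # duplicate-free
    assert texts == [s.expression_text for s in enumerate_candidates()]  # deterministic


def test_enumerated_specs_are_all_valid_and_contain_builtins():
    enumerated = {s.expression_text for s in enumerate_candidates()}
    for b in builtin_algorithms():
        if b.id in ("A1", "A6"):  # pure independent-atom compositions
            assert b.expression_text in enumerated
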