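"""Agreement analysis and evaluation against synthetic ground truth."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from casefinder.agreement import (
    agreement,
    evaluate_against_truth,
    pairwise_overlap,
)
from casefinder.engine import CohortResult, parse_algorithm, evaluate
from casefinder.model import AnalysisWindow
from casefinder.atoms import compute_all_atoms
from casefinder.synthetic import AtomNoise, GeneratorConfig, generate

from conftest import WINDOW


def _c(alg, members, window=WINDOW):
    return CohortResult(alg, window, frozenset(members))


# ---------------------------------------------------------------------------
# agreement


def test_single_cohort_agreement_is_trivial():
    t = agreement([_c("A", {"x", "y", "z"})])
    assert t.n_exactly == (3,) and t.n_at_least == (3,)
    assert t.union_size == 3 and t.core_set == {"x", "y", "z"}


def test_hand_counted_three_cohort_example():
    """Cohorts {A,B}, {A,C}, {A}: A is flagged by all three, B and C by
    exactly one each."""
    t = agreement([_c("c1", {"A", "B"}), _c("c2", {"A", "C"}), _c("c3", {"A"})])
    assert t.n_exactly == (2, 0, 1)
    assert t.n_at_least == (3, 1, 1)
    assert t.core_set == {"A"}
    assert t.union_size == 3


def test_agreement_mixed_windows_rejected():
    other = AnalysisWindow("2017-2018", date(2017, 4, 1), date(2018, 4, 1))
    with pytest.raises(ValueError, match="windows"):
        agreement([_c("a", {"x"}), _c("b", {"x"}, window=other)])


def test_agreement_matches_bitset_multiplicity_oracle():
    """12 random cohorts over 1000 patients vs per-patient counting."""
    rng = np.random.default_rng(66)
    pids = [f"P{i:04d}" for i in range(1000)]
    cohorts = [
        _c(f"c{k}", rng.choice(pids, size=int(rng.integers(0, 600)),
                               replace=False))
        for k in range(12)
    ]
    t = agreement(cohorts)
    mult = {p: sum(p in c.patients for c in cohorts) for p in pids}
    flagged = {p for p, m in mult.items() if m}
    assert t.union_size == len(flagged)
    for k in range(1, 13):
        assert t.n_exactly[k - 1] == sum(1 for m in mult.values() if m == k)
        assert t.n_at_least[k - 1] == sum(1 for m in mult.values() if m >= k)
    assert t.core_set == {p for p, m in mult.items() if m == 12}
    # conservation and monotonicity
    assert sum(t.n_exactly) == t.union_size
    assert all(a >= b for a, b in zip(t.n_at_least, t.n_at_least[1:]))


# ---------------------------------------------------------------------------
# pairwise overlap


def test_identical_cohorts_have_jaccard_one_and_disjoint_zero():
    inter, jac = pairwise_overlap(
        [_c("a", {"x", "y"}), _c("b", {"x", "y"}), _c("d", {"z"})]
    )
    assert jac.loc["a", "b"] == 1.0
    assert jac.loc["a", "d"] == 0.0
    assert inter.loc["a", "b"] == 2 and inter.loc["a", "d"] == 0
    assert (jac.values == jac.values.T).all()
    assert jac.loc["a", "a"] == 1.0


def test_pairwise_matches_set_oracle():
    rng = np.random.default_rng(9)
    pids = [f"P{i}" for i in range(200)]
    cohorts = [
        _c(f"c{k}", rng.choice(pids, size=int(rng.integers(1, 150)),
                               replace=False))
        for k in range(5)
    ]
    inter, jac = pairwise_overlap(cohorts)
    for i, a in enumerate(cohorts):
        for j, b in enumerate(cohorts):
            n_int = len(a.patients & b.patients)
            n_uni = len(a.patients | b.patients)
            assert inter.iloc[i, j] == n_int
            assert jac.iloc[i, j] == pytest.approx(n_int / n_uni)


# ---------------------------------------------------------------------------
# evaluation against truth


def _truth(cases, population):
    return pd.DataFrame({
        "patient_id": list(population),
        "is_true_case": [p in cases for p in population],
        "is_incident": False,
    })


def test_perfect_classifier_metrics():
    pop = {f"P{i}" for i in range(10)}
    cases = {"P1", "P2"}
    m = evaluate_against_truth(_c("a", cases), _truth(cases, pop), pop)
    assert (m.tp, m.fp, m.fn) == (2, 0, 0)
    assert m.sensitivity == 1.0 and m.ppv == 1.0


def test_hand_computed_confusion_table():
    """Truth {A,B,C,D}, cohort {A,B,E}, population of 10."""
    pop = {"A", "B", "C", "D", "E", "F", "G", "H", "I", "J"}
    cases = {"A", "B", "C", "D"}
    m = evaluate_against_truth(_c("x", {"A", "B", "E"}), _truth(cases, pop), pop)
    assert (m.tp, m.fp, m.fn, m.tn) == (2, 1, 2, 5)
    assert m.sensitivity == pytest.approx(0.5)
    assert m.ppv == pytest.approx(2 / 3)
    assert m.specificity == pytest.approx(5 / 6)


def test_empty_cohort_ppv_is_undefined_not_zero():
    pop = {"A", "B"}
    m = evaluate_against_truth(_c("x", set()), _truth({"A"}, pop), pop)
    assert m.ppv is None and "ppv" in m.undefined
    assert m.sensitivity == 0.0


def test_cohort_member_missing_from_truth_errors():
    pop = {"A", "B"}
    with pytest.raises(ValueError, match="absent from ground truth"):
        evaluate_against_truth(_c("x", {"Z"}), _truth({"A"}, pop), pop | {"Z"})


def test_dx_only_sensitivity_tracks_configured_recording_probability():
    """With sens_DX=0.6 and all false-positive rates zero, a DX-only
    algorithm's empirical sensitivity is binomially distributed around 0.6."""
    noise = {a: AtomNoise(0.0, 0.0) for a in
             ("R01", "R02", "R18", "CLUSTER", "HONOS", "FEP", "EIP")}
    noise["DX"] = AtomNoise(0.6, 0.0)
    cfg = GeneratorConfig(n_patients=50_000, true_prevalence=0.003,
                          atom_noise=noise, seed=33)
    tables, truth = generate(cfg)
    atoms = compute_all_atoms(tables, cfg.window)
    cohort = evaluate(parse_algorithm("DX", id="dx"), atoms, cfg.window)
    pop = frozenset(truth["patient_id"])
    m = evaluate_against_truth(cohort, truth, pop)
    n_cases = m.tp + m.fn
    assert m.fp == 0
    sd = np.sqrt(0.6 * 0.4 / n_cases)
    assert abs(m.sensitivity - 0.6) <= 4 * sd


def test_or_terms_trade_sensitivity_for_specificity():
    """Adding an OR term can only raise sensitivity and lower specificity:
    the expressions are nested, so the cohorts are nested."""
    cfg = GeneratorConfig(n_patients=30_000, true_prevalence=0.003, seed=8)
    tables, truth = generate(cfg)
    atoms = compute_all_atoms(tables, cfg.window)
    pop = frozenset(truth["patient_id"])
    sens_prev, spec_prev = -1.0, 2.0
    for text in ("DX", "DX OR FEP", "DX OR FEP OR EIP",
                 "DX OR FEP OR EIP OR R02"):
        cohort = evaluate(parse_algorithm(text, id=text), atoms, cfg.window)
        m = evaluate_against_truth(cohort, truth, pop)
        assert m.sensitivity >= sens_prev
        assert m.specificity <= spec_prev
        sens_prev, spec_prev = m.sensitivity, m.specificity
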