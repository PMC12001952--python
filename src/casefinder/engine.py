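"""Boolean case-finding algorithm engine.

An algorithm is a boolean expression over the eight criteria atoms: elements
judged usable on their own (primary diagnosis, referral code 02, FEP flag,
EIP flag) combine with OR, while joint-only elements (clusters, HoNOS,
referral codes 01 and 18) may only contribute inside an AND composite —
referral code 18 (in crisis) specifically must be AND-joined with the EIP
flag.  Evaluation is plain set algebra: OR is union, AND is intersection,
and the resulting cohort is deduplicated by patient identifier, so a patient
satisfying several branches is counted once.

Four compositions are shipped as built-ins (A1, A5, A6, A7); any other
algorithm can be supplied as an expression string, e.g.::

    parse_algorithm("DX OR R02 OR (CLUSTER AND HONOS)", id="custom")

Age filtering follows the case-definition rules: incident cohorts keep ages
14-65 at the first qualifying record, prevalent cohorts ages 14-105, and
under-14s are always removed.  A separate exclusion removes 55-65-year-olds
whose first-episode evidence coincides with a dementia or psychotic-
depression diagnosis, to avoid counting psychotic dementia as psychosis.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .atoms import ATOM_LABELS, INDEPENDENT_ATOMS, JOINT_ONLY_ATOMS, AtomResult
from .model import AnalysisWindow, CodeSet, age_at
from . import vocab

__all__ = [
    "Leaf", "And", "Or", "Node",
    "AlgorithmSpec", "CohortResult",
    "parse_algorithm", "builtin_algorithms", "evaluate",
    "qualifying_dates", "apply_age_filter", "apply_older_age_exclusion",
    "enumerate_candidates",
]


# ---------------------------------------------------------------------------
# Expression trees


@dataclass(frozen=True)
class Leaf:
    label: str

    def __str__(self) -> str:
        return self.label

    def leaves(self) -> frozenset[str]:
        return frozenset({self.label})


@dataclass(frozen=True)
class _NAry:
    children: tuple

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise ValueError(f"{type(self).__name__} needs at least two children")
        # canonical child order -> deterministic repr, hashing, enumeration
        object.__setattr__(
            self, "children", tuple(sorted(self.children, key=str))
        )

    def leaves(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for c in self.children:
            out |= c.leaves()
        return out


class Or(_NAry):
    _op = "OR"

    def __str__(self) -> str:
        return " OR ".join(
            f"({c})" if isinstance(c, And) else str(c) for c in self.children
        )


class And(_NAry):
    _op = "AND"

    def __str__(self) -> str:
        return " AND ".join(
            f"({c})" if isinstance(c, Or) else str(c) for c in self.children
        )


Node = Leaf | Or | And


@dataclass(frozen=True)
class AlgorithmSpec:
    """A validated case-finding algorithm."""

    id: str
    expression: Node
    mode: str = "prevalent"  # "incident" | "prevalent"

    def __post_init__(self) -> None:
        if self.mode not in ("incident", "prevalent"):
            raise ValueError(f"unknown mode {self.mode!r}")
        _validate_tree(self.expression)

    @property
    def expression_text(self) -> str:
        return str(self.expression)

    def leaves(self) -> frozenset[str]:
        return self.expression.leaves()


@dataclass(frozen=True)
class CohortResult:
    """Deduplicated patient set selected by one algorithm in one window."""

    algorithm_id: str
    window: AnalysisWindow
    patients: frozenset[str]

    @property
    def count(self) -> int:
        return len(self.patients)


# ---------------------------------------------------------------------------
# Parsing and structural validation

_TOKEN_RE = re.compile(r"\s*(\(|\)|[A-Za-z][A-Za-z0-9_+]*)")


def _tokenise(text: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip():
                raise ValueError(f"cannot parse expression at: {text[pos:]!r}")
            break
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive descent over: expr := term (OR term)*; term := factor (AND
    factor)*; factor := ATOM | '(' expr ')'."""

    def __init__(self, tokens: list[str]):
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise ValueError("unexpected end of expression")
        self.pos += 1
        return tok

    def expr(self) -> Node:
        parts = [self.term()]
        while self.peek() and self.peek().upper() == "OR":
            self.take()
            parts.append(self.term())
        return parts[0] if len(parts) == 1 else Or(tuple(_flatten(parts, Or)))

    def term(self) -> Node:
        parts = [self.factor()]
        while self.peek() and self.peek().upper() == "AND":
            self.take()
            parts.append(self.factor())
        return parts[0] if len(parts) == 1 else And(tuple(_flatten(parts, And)))

    def factor(self) -> Node:
        tok = self.take()
        if tok == "(":
            node = self.expr()
            if self.take() != ")":
                raise ValueError("unbalanced parentheses")
            return node
        if tok == ")":
            raise ValueError("unexpected ')'")
        label = tok.upper()
        if label in ("AND", "OR"):
            raise ValueError(f"misplaced operator {label}")
        if label not in ATOM_LABELS:
            raise ValueError(
                f"unknown atom label {tok!r}; expected one of {', '.join(ATOM_LABELS)}"
            )
        return Leaf(label)


def _flatten(parts: Sequence[Node], cls: type) -> list[Node]:
    out: list[Node] = []
    for p in parts:
        out.extend(p.children) if isinstance(p, cls) else out.append(p)
    return out


def _or_terms(node: Node) -> list[Node]:
    """Top-level OR terms, looking through nested ORs."""
    if isinstance(node, Or):
        terms: list[Node] = []
        for c in node.children:
            terms.extend(_or_terms(c))
        return terms
    return [node]


def _validate_tree(
    node: Node, joint_only: frozenset[str] = JOINT_ONLY_ATOMS
) -> None:
    """Reject expressions where a joint-only element could select patients on
    its own, and require referral code 18 to be AND-joined with the EIP flag."""
    for term in _or_terms(node):
        if isinstance(term, Leaf) and term.label in joint_only:
            raise ValueError(
                f"atom {term.label} is joint-only: it cannot stand alone as an "
                "OR term; combine it with AND"
            )
    _check_r18(node)


def _check_r18(node: Node) -> None:
    if isinstance(node, Leaf):
        return
    for c in node.children:
        _check_r18(c)
    if isinstance(node, And):
        labels = node.leaves()
        if "R18" in labels and "EIP" not in labels:
            raise ValueError(
                "R18 (referral: in crisis) carries no diagnosis and must be "
                "AND-joined with the EIP flag"
            )


def parse_algorithm(
    text: str,
    id: str = "custom",
    mode: str = "prevalent",
    joint_only: frozenset[str] = JOINT_ONLY_ATOMS,
) -> AlgorithmSpec:
    """Parse and validate an algorithm expression string.

    Raises ``ValueError`` on unknown labels, malformed syntax, or violation
    of the joint-use constraints (naming the offending atom).
    """
    tokens = _tokenise(text)
    if not tokens:
        raise ValueError("empty expression")
    parser = _Parser(tokens)
    tree = parser.expr()
    if parser.peek() is not None:
        raise ValueError(f"trailing input at token {parser.peek()!r}")
    _validate_tree(tree, joint_only)
    return AlgorithmSpec(id=id, expression=tree, mode=mode)


def builtin_algorithms(mode: str = "prevalent") -> list[AlgorithmSpec]:
    """The four compositions shipped as built-ins.

    A1 uses all four independently usable elements; A6 is the leanest
    (three elements); A5 and A7 add the (clusters AND HoNOS) composite.
    Other compositions load from configuration.
    """
    texts = {
        "A1": "DX OR R02 OR FEP OR EIP",
        "A5": "DX OR R02 OR FEP OR (CLUSTER AND HONOS)",
        "A6": "DX OR FEP OR EIP",
        "A7": "DX OR FEP OR EIP OR (CLUSTER AND HONOS)",
    }
    return [parse_algorithm(t, id=i, mode=mode) for i, t in texts.items()]


# ---------------------------------------------------------------------------
# Evaluation


def _eval_node(node: Node, atoms: Mapping[str, AtomResult]) -> frozenset[str]:
    if isinstance(node, Leaf):
        if node.label not in atoms:
            raise KeyError(f"atom {node.label} missing from the supplied results")
        return atoms[node.label].patients
    sets = [_eval_node(c, atoms) for c in node.children]
    if isinstance(node, Or):
        return frozenset().union(*sets)
    return frozenset.intersection(*sets)


def evaluate(
    spec: AlgorithmSpec, atoms: Mapping[str, AtomResult], window: AnalysisWindow
) -> CohortResult:
    """Evaluate an algorithm over atom results for one window.

    OR maps to set union and AND to set intersection, so double counting is
    impossible by construction: the cohort is a set of patient identifiers.
    """
    for label in spec.leaves():
        if label not in atoms:
            raise KeyError(f"atom {label} missing for window {window.label!r}")
        if atoms[label].window != window:
            raise ValueError(
                f"atom {label} was computed for window "
                f"{atoms[label].window.label!r}, not {window.label!r}"
            )
    return CohortResult(spec.id, window, _eval_node(spec.expression, atoms))


def _qual_date(node: Node, atoms: Mapping[str, AtomResult], pid: str) -> date | None:
    """Earliest date at which the patient satisfies the expression.

    A leaf is satisfied at its first qualifying record; an AND composite only
    once *all* its parts hold (max of part dates); an OR at the earliest
    satisfied branch (min).
    """
    if isinstance(node, Leaf):
        return atoms[node.label].first_dates.get(pid)
    dates = [_qual_date(c, atoms, pid) for c in node.children]
    if isinstance(node, And):
        return None if any(d is None for d in dates) else max(dates)
    hits = [d for d in dates if d is not None]
    return min(hits) if hits else None


def qualifying_dates(
    spec: AlgorithmSpec,
    atoms: Mapping[str, AtomResult],
    cohort: CohortResult,
) -> dict[str, date]:
    """Per-patient date at which the algorithm's criterion was first met."""
    out = {}
    for pid in cohort.patients:
        d = _qual_date(spec.expression, atoms, pid)
        if d is None:
            raise ValueError(f"cohort member {pid!r} has no qualifying record date")
        out[pid] = d
    return out


# ---------------------------------------------------------------------------
# Age and exclusion filters

#: inclusive age bounds at the qualifying date, by mode
AGE_BOUNDS = {"incident": (14, 65), "prevalent": (14, 105)}


def apply_age_filter(
    cohort: CohortResult,
    patients: pd.DataFrame,
    mode: str,
    qual_dates: Mapping[str, date],
) -> CohortResult:
    """Retain cohort members inside the mode's age band at their qualifying
    date: 14-65 for incident cohorts, 14-105 for prevalent; under-14s are
    excluded in both modes."""
    if mode not in AGE_BOUNDS:
        raise ValueError(f"unknown mode {mode!r}")
    lo, hi = AGE_BOUNDS[mode]
    births = patients.set_index(patients["patient_id"].astype(str))["birth_date"]
    kept = set()
    for pid in cohort.patients:
        if pid not in qual_dates:
            raise ValueError(f"cohort member {pid!r} has no qualifying date")
        if pid not in births.index or pd.isna(births[pid]):
            raise ValueError(f"cohort member {pid!r} has no birth date")
        a = age_at(births[pid].date(), qual_dates[pid])
        if lo <= a <= hi:
            kept.add(pid)
    return CohortResult(cohort.algorithm_id, cohort.window, frozenset(kept))


def apply_older_age_exclusion(
    cohort: CohortResult,
    patients: pd.DataFrame,
    diagnoses: pd.DataFrame,
    exclusion_codesets: Sequence[CodeSet] = (
        vocab.DEMENTIA_ICD10,
        vocab.PSYCHOTIC_DEPRESSION_ICD10,
    ),
    *,
    window: AnalysisWindow,
    qual_dates: Mapping[str, date],
    age_band: tuple[int, int] = (55, 65),
    first_episode_members: frozenset[str] | None = None,
    strict: bool = False,
) -> CohortResult:
    """Remove likely psychotic-dementia / psychotic-depression cases.

    A member is excluded iff their qualifying evidence falls at ages 55-65
    AND they carry an in-window diagnosis (any rank) in one of the exclusion
    code sets.  By default only members whose evidence is first-episode
    (``first_episode_members``, e.g. the union of the FEP-flag and
    referral-01 atoms) are subject to the rule; ``strict=True`` applies it to
    every member.
    """
    lo, hi = age_band
    mask = window.mask(diagnoses["record_date"])
    excl_mask = pd.Series(False, index=diagnoses.index)
    for cs in exclusion_codesets:
        excl_mask = excl_mask | cs.mask(diagnoses["code"])
    flagged = set(diagnoses.loc[mask & excl_mask, "patient_id"].astype(str))

    births = patients.set_index(patients["patient_id"].astype(str))["birth_date"]
    subject = cohort.patients if strict or first_episode_members is None else (
        cohort.patients & first_episode_members
    )
    removed = set()
    for pid in subject:
        if pid not in flagged or pid not in qual_dates:
            continue
        if pid in births.index and not pd.isna(births[pid]):
            a = age_at(births[pid].date(), qual_dates[pid])
            if lo <= a <= hi:
                removed.add(pid)
    return CohortResult(
        cohort.algorithm_id, cohort.window, cohort.patients - frozenset(removed)
    )


# ---------------------------------------------------------------------------
# Candidate enumeration


def enumerate_candidates(
    independent: Sequence[str] = tuple(sorted(INDEPENDENT_ATOMS)),
    composites: Sequence[Node] = (
        And((Leaf("CLUSTER"), Leaf("HONOS"))),
        And((Leaf("FEP"), Leaf("R01"))),
        And((Leaf("EIP"), Leaf("R18"))),
    ),
    mode: str = "prevalent",
) -> list[AlgorithmSpec]:
    """Enumerate every OR-combination of at least one independently usable
    element with any subset of the joint composites.

    The enumeration is deterministic (canonically ordered) and duplicate-free;
    its length under the default inventory is reported, not pinned, because
    different joint-use inventories yield different counts.
    """
    if not independent:
        raise ValueError("at least one independently usable atom is required")
    ind = sorted(set(independent))
    specs: list[AlgorithmSpec] = []
    n = 0
    for r in range(1, len(ind) + 1):
        for chosen in itertools.combinations(ind, r):
            for k in range(len(composites) + 1):
                for comps in itertools.combinations(composites, k):
                    parts: list[Node] = [Leaf(a) for a in chosen] + list(comps)
                    tree = parts[0] if len(parts) == 1 else Or(tuple(parts))
                    n += 1
                    specs.append(
                        AlgorithmSpec(id=f"C{n:03d}", expression=tree, mode=mode)
                    )
    return specs
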