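"""Association rules and interestingness measures.

A rule A → B (antecedent A, single-item consequent B, A ∩ B = ∅) is scored
with

* support   P(A, B) — joint prevalence,
* confidence P(B | A),
* lift      L = P(A, B) / (P(A) P(B)) — 1 under independence,
* standardized lift L* = (L − λ) / (ν − λ),

where the bounds come from Fréchet inequalities combined with the mining
thresholds σ (minimum support) and κ (minimum confidence):

    ν = 1 / max{P(A), P(B)}
    λ = max{ (P(A)+P(B)−1) / (P(A) P(B)),
             4σ / (1+σ)²,
             σ / (P(A) P(B)),
             κ / P(B) }.

For any rule that satisfies both thresholds, λ ≤ L ≤ ν, so L* lies in [0, 1];
it rescales the raw lift onto the range actually attainable given the
marginals and thresholds, which makes rules with very different prevalences
comparable. All probabilities are carried at full precision; rounding happens
only in report formatting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .apriori import FrequentItemSetTable
from .transactions import TransactionMatrix

__all__ = [
    "AssociationRule",
    "RuleMetrics",
    "ScoredRule",
    "lift_bounds",
    "standardized_lift_value",
    "lift",
    "standardized_lift",
    "generate_rules",
    "rank_rules",
    "rules_to_frame",
]


@dataclass(frozen=True)
class AssociationRule:
    antecedent: frozenset[str]
    consequent: frozenset[str]

    def __post_init__(self) -> None:
        if not self.antecedent:
            raise ValueError("antecedent must be nonempty")
        if not self.consequent:
            raise ValueError("consequent must be nonempty")
        if self.antecedent & self.consequent:
            raise ValueError("antecedent and consequent must be disjoint")

    def __str__(self) -> str:
        return f"{{{','.join(sorted(self.antecedent))}}} -> {{{','.join(sorted(self.consequent))}}}"


@dataclass(frozen=True)
class RuleMetrics:
    support: float
    confidence: float
    lift: float
    lambda_bound: float
    nu_bound: float
    standardized_lift: float | None  # None when ν == λ (degenerate bounds)
    min_support_used: float
    min_confidence_used: float


ScoredRule = tuple[AssociationRule, RuleMetrics]


def lift_bounds(
    p_a: float, p_b: float, min_support: float, min_confidence: float
) -> tuple[float, float]:
    """Lower (λ) and upper (ν) bound of the lift given marginals and thresholds."""
    if not (0 < p_a <= 1 and 0 < p_b <= 1):
        raise ValueError("marginal probabilities must lie in (0, 1]")
    sigma, kappa = min_support, min_confidence
    nu = 1.0 / max(p_a, p_b)
    lam = max(
        (p_a + p_b - 1.0) / (p_a * p_b),
        4.0 * sigma / (1.0 + sigma) ** 2,
        sigma / (p_a * p_b),
        kappa / p_b,
    )
    return lam, nu


def standardized_lift_value(lift_value: float, lam: float, nu: float) -> float | None:
    """(L − λ)/(ν − λ); None when the bounds coincide (undefined, not 0/0)."""
    if math.isclose(nu, lam, rel_tol=0.0, abs_tol=1e-12):
        return None
    return (lift_value - lam) / (nu - lam)


def _probability(T: TransactionMatrix, items: frozenset[str]) -> float:
    mask = None
    for item in items:
        col = T.column(item).astype(bool)
        mask = col if mask is None else (mask & col)
    assert mask is not None
    return mask.sum() / T.n


def lift(rule: AssociationRule, T: TransactionMatrix) -> float:
    """P(A, B) / (P(A) P(B)) computed from the transaction matrix."""
    p_a = _probability(T, rule.antecedent)
    p_b = _probability(T, rule.consequent)
    if p_a == 0 or p_b == 0:
        raise ValueError("zero marginal probability")
    p_ab = _probability(T, rule.antecedent | rule.consequent)
    return p_ab / (p_a * p_b)


def standardized_lift(
    rule: AssociationRule,
    T: TransactionMatrix,
    min_support: float,
    min_confidence: float,
) -> tuple[float, float, float | None]:
    """(λ, ν, L*) for a rule evaluated on a transaction matrix."""
    p_a = _probability(T, rule.antecedent)
    p_b = _probability(T, rule.consequent)
    lam, nu = lift_bounds(p_a, p_b, min_support, min_confidence)
    return lam, nu, standardized_lift_value(lift(rule, T), lam, nu)


def generate_rules(
    freq: FrequentItemSetTable, min_confidence: float
) -> list[ScoredRule]:
    """Single-consequent rules from frequent itemsets at threshold κ.

    Every frequent itemset S with |S| ≥ 2 contributes, for each b ∈ S, the
    candidate rule S∖{b} → {b}; it is emitted iff its confidence
    support(S)/support(S∖{b}) ≥ κ. Marginals needed for the lift bounds are
    read off the table itself (downward closure guarantees they are present).
    """
    if not 0 < min_confidence <= 1:
        raise ValueError("min_confidence must lie in (0, 1]")
    supports = dict(freq.entries)
    scored: list[ScoredRule] = []
    for itemset, s_joint in freq.entries:
        if len(itemset) < 2:
            continue
        for b in sorted(itemset):
            antecedent = itemset - {b}
            consequent = frozenset((b,))
            p_a = supports[antecedent]
            p_b = supports[consequent]
            confidence = s_joint / p_a
            if confidence < min_confidence:
                continue
            lift_value = s_joint / (p_a * p_b)
            lam, nu = lift_bounds(p_a, p_b, freq.min_support, min_confidence)
            scored.append(
                (
                    AssociationRule(antecedent, consequent),
                    RuleMetrics(
                        support=s_joint,
                        confidence=confidence,
                        lift=lift_value,
                        lambda_bound=lam,
                        nu_bound=nu,
                        standardized_lift=standardized_lift_value(lift_value, lam, nu),
                        min_support_used=freq.min_support,
                        min_confidence_used=min_confidence,
                    ),
                )
            )
    return rank_rules(scored)


def _rank_key(entry: ScoredRule):
    rule, m = entry
    undefined = m.standardized_lift is None
    lstar = -math.inf if undefined else m.standardized_lift
    return (undefined, -lstar, -m.support, tuple(sorted(rule.antecedent)),
            tuple(sorted(rule.consequent)))


def rank_rules(rules: list[ScoredRule]) -> list[ScoredRule]:
    """Descending standardized lift; ties by support then antecedent; rules
    with undefined L* sink to the bottom. Deterministic for any input order."""
    return sorted(rules, key=_rank_key)


def rules_to_frame(rules: list[ScoredRule], display: bool = False) -> pd.DataFrame:
    """Tabulate scored rules; ``display=True`` adds 2-decimal report columns."""
    records = []
    for rule, m in rules:
        rec = {
            "antecedent": ";".join(sorted(rule.antecedent)),
            "consequent": ";".join(sorted(rule.consequent)),
            "support": m.support,
            "confidence": m.confidence,
            "lift": m.lift,
            "lambda": m.lambda_bound,
            "nu": m.nu_bound,
            "standardized_lift": m.standardized_lift,
        }
        if display:
            rec.update(
                {
                    "support_2dp": round(m.support, 2),
                    "confidence_2dp": round(m.confidence, 2),
                    "lift_2dp": round(m.lift, 2),
                    "standardized_lift_2dp": (
                        None if m.standardized_lift is None
                        else round(m.standardized_lift, 2)
                    ),
                }
            )
        records.append(rec)
    return pd.DataFrame.from_records(records)


def save_rules(rules: list[ScoredRule], path: str | Path) -> None:
    rules_to_frame(rules, display=True).to_csv(path, index=False)
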