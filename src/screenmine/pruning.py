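"""Redundancy pruning of association rules, clustered by consequent.

Rules sharing a consequent are grouped, and within each group a rule is
*redundant* when its antecedent is a proper subset of another member's
antecedent — the shorter rule carries no itemset information not already in
its super rule. Pruning keeps exactly the antecedent-maximal rules; it is
pure selection, so retained rules keep the metrics they were mined with.
"""

from __future__ import annotations

from dataclasses import dataclass

from .rules import ScoredRule

__all__ = ["RuleCluster", "PruningSummary", "cluster_by_consequent",
           "prune_redundant", "prune_all"]


@dataclass(frozen=True)
class RuleCluster:
    consequent: str
    members: tuple[ScoredRule, ...]

    def __post_init__(self) -> None:
        antecedents = [rule.antecedent for rule, _ in self.members]
        if len(set(antecedents)) != len(antecedents):
            raise ValueError("duplicate antecedents within a cluster")
        for rule, _ in self.members:
            if rule.consequent != frozenset((self.consequent,)):
                raise ValueError("cluster member with mismatched consequent")


@dataclass(frozen=True)
class PruningSummary:
    n_input: int
    n_retained: int

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_retained

    @property
    def redundancy_fraction(self) -> float:
        return self.n_removed / self.n_input if self.n_input else 0.0


def cluster_by_consequent(rules: list[ScoredRule]) -> list[RuleCluster]:
    """One cluster per distinct consequent, preserving rule order."""
    grouped: dict[str, list[ScoredRule]] = {}
    for rule, metrics in rules:
        if len(rule.consequent) != 1:
            raise ValueError(f"multi-item consequent in rule {rule}")
        (item,) = rule.consequent
        grouped.setdefault(item, []).append((rule, metrics))
    return [RuleCluster(item, tuple(members)) for item, members in grouped.items()]


def prune_redundant(cluster: RuleCluster) -> RuleCluster:
    """Drop every rule whose antecedent is a proper subset of another member's."""
    antecedents = [rule.antecedent for rule, _ in cluster.members]
    kept = tuple(
        (rule, m)
        for rule, m in cluster.members
        if not any(rule.antecedent < other for other in antecedents)
    )
    return RuleCluster(cluster.consequent, kept)


def prune_all(rules: list[ScoredRule]) -> tuple[list[ScoredRule], PruningSummary]:
    """Per-consequent pruning over a whole rule list, keeping input order."""
    clusters = cluster_by_consequent(rules)
    retained = {
        rule
        for cluster in clusters
        for rule, _ in prune_redundant(cluster).members
    }
    # Filtering the original list keeps the ranked ordering stable.
    kept = [(rule, m) for rule, m in rules if rule in retained]
    return kept, PruningSummary(n_input=len(rules), n_retained=len(kept))
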