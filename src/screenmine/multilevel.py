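"""Multilevel (category-level) association rules.

Items are first collapsed to one indicator per clinical category — the
category is "present" when any of its member items is — and the ordinary
mining machinery then runs on the 3-column matrix. Category rules are ranked
by lift (category tables are conventionally reported without standardized
lift, though it is still computed and carried along), with support and
confidence reported as percentages.
"""

from __future__ import annotations

import pandas as pd

from .apriori import apriori
from .rules import ScoredRule, generate_rules
from .transactions import ItemCatalog, TransactionMatrix, categorize

__all__ = ["multilevel_rules", "category_rule_table"]


def multilevel_rules(
    T: TransactionMatrix,
    catalog: ItemCatalog,
    min_support: float,
    min_confidence: float,
) -> list[ScoredRule]:
    """Mine rules over category indicators; ranked by descending lift."""
    if len(catalog.categories) < 2:
        raise ValueError("catalog must define at least 2 categories")
    cat_matrix = categorize(T, catalog)
    freq = apriori(cat_matrix, min_support)
    scored = generate_rules(freq, min_confidence)
    return sorted(
        scored,
        key=lambda e: (
            -e[1].lift,
            -e[1].support,
            tuple(sorted(e[0].antecedent)),
            tuple(sorted(e[0].consequent)),
        ),
    )


def category_rule_table(rules: list[ScoredRule]) -> pd.DataFrame:
    """Report table: support/confidence as % (1 decimal), lift to 2 decimals."""
    records = []
    for rule, m in rules:
        records.append(
            {
                "antecedent": ";".join(sorted(rule.antecedent)),
                "consequent": ";".join(sorted(rule.consequent)),
                "support_pct": round(100.0 * m.support, 1),
                "confidence_pct": round(100.0 * m.confidence, 1),
                "lift": round(m.lift, 2),
                "standardized_lift": (
                    None if m.standardized_lift is None
                    else round(m.standardized_lift, 2)
                ),
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=["antecedent", "consequent", "support_pct", "confidence_pct",
                 "lift", "standardized_lift"],
    )
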