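"""Multilevel association rules between screening categories.

Items are collapsed to 3 indicators — any vitals item present, any
laboratory item present, any lifestyle item present — and rules are mined
between those indicators, ranked by lift.
"""

from screenmine import generate, study_catalog, study_default_config
from screenmine.multilevel import category_rule_table, multilevel_rules

T = generate(study_default_config(n=92_140, seed=7))
rules = multilevel_rules(T, study_catalog(), min_support=0.02,
                         min_confidence=0.80)
print(category_rule_table(rules).to_string(index=False))
print("\nEvery lift exceeds 1: recording any screen in one clinical category "
      "raises the chance that another category is recorded too.")
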