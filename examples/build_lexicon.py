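"""Build the default risk-factor lexicon and inspect its structure.

The default vocabulary holds 23 named risk-factor groups in three
categories (general environmental, specific environmental, other), each
expanded into explicit surface variants; all-caps acronyms are flagged for
case-sensitive matching.
"""

from termsweep import build_default_lexicon

lexicon = build_default_lexicon()
summary = lexicon.summary()
print(f"groups: {summary['n_groups']}")
print(f"variants: {summary['n_variants']} "
      f"({summary['n_printed_variants']} from the published term table)")
for category, n in summary["groups_by_category"].items():
    print(f"  {category}: {n} groups")

print("\nexample groups:")
for name in ("Pesticides", "Endocrine disrupting chemicals", "Exercise"):
    g = lexicon.group(name)
    print(f"  {g.factor_name} [{g.category}]: {', '.join(g.variants)}")

# The counts above say: 23 factors, 52 published surface forms plus 3
# supplementary spellings, split 3 / 10 / 10 across the categories.
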