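"""Extract visible text from an HTML page and count term-group mentions.

Demonstrates the matching semantics: script/style/comment content is
invisible, multi-word phrases tolerate hyphens, acronyms are
case-sensitive, and the four ambiguous terms excluded from the lexicon
("environment", "toxic", "chemical", "hormone therapy") never count.
"""

from termsweep import build_default_lexicon, count_group_mentions, extract_visible_text

HTML = """
<html><head><title>Risk factors</title>
<script>var hidden = "BPA BPA BPA";</script>
<!-- pesticides in a comment do not count -->
</head><body>
<p>Regular exercise and physical activity reduce risk. Avoiding
endocrine-disrupting chemicals such as BPA and phthalates may also help.
Chemotherapy can be toxic, and the environment matters, but those words
alone are ambiguous. DES exposure before birth is a known risk; des moines
is just a city.</p>
</body></html>
"""

lexicon = build_default_lexicon()
text = extract_visible_text(HTML)
print("visible text:", text[:70], "...")
print()
for g in lexicon:
    n = count_group_mentions(text, g)
    if n:
        print(f"{g.factor_name}: {n}")

# Expected: Exercise 2 (exercise + physical activity), Endocrine
# disrupting chemicals 1, Bisphenols 1 (visible BPA only), Phthalates 1,
# Diethylstilbestrol 1 (uppercase DES only) — and nothing from the
# script, the comment, or the ambiguous standalone words.
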