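"""Independent brute-force counting oracle.

Character-level reference implementation of the group-mention count: at
every character position try every variant with an anchored regex, take
the longest match, and skip past it (non-overlapping).  Deliberately
shares no code with the package's token-based matcher.
"""

from __future__ import annotations

import re

_GAP = r"[\s\-‐‑–]+"


def _variant_regexes(group):
    out = []
    for variant, acronym in zip(group.variants, group.acronym_flags):
        pattern = _GAP.join(re.escape(tok) for tok in variant.split())
        flags = re.UNICODE if acronym else re.UNICODE | re.IGNORECASE
        out.append(re.compile(pattern, flags))
    return out


def _is_word_char(ch: str) -> bool:
    # mirrors the letter/digit token definition: alnum, but not underscore
    return ch.isalnum()


def brute_force_count(text: str, group) -> int:
    """Count non-overlapping, longest-match-wins mentions of *group*."""
    regexes = _variant_regexes(group)
    i = 0
    count = 0
    n = len(text)
    while i < n:
        if i > 0 and _is_word_char(text[i - 1]):
            i += 1
            continue
        best = 0
        for rx in regexes:
            m = rx.match(text, i)
            if m is None:
                continue
            end = m.end()
            if end < n and _is_word_char(text[end]):
                continue  # word boundary violated at the right edge
            if end - i > best:
                best = end - i
        if best:
            count += 1
            i += best
        else:
            i += 1
    return count
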