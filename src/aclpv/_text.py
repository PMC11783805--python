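"""Text normalization shared by name/term lookups.

Spontaneous-report tables carry verbatim ingredient names and MedDRA
preferred terms; lookups should be robust to trivial whitespace and case
variation, and nothing more.  No fuzzy matching: a near-miss match would
silently inflate anticholinergic scores.
"""


def normalize(text: str) -> str:
    """Trim surrounding whitespace and case-fold.

    The normalized form is the lookup key for drug names and preferred
    terms throughout the package.
    """
    return str(text).strip().casefold()
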