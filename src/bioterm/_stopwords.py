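"""Closed list of English function words.

Function words never count as content lemmas: they are excluded from
candidate grouping keys, seed terms, lexicon bags and variant-matching
anchors, but they may appear as inserted material inside a variant window
(e.g. the connective in "diseases including infectious").
"""

STOP_WORDS: frozenset[str] = frozenset(
    """
    a an the this that these those it its their his her our your my
    i you he she we they them us him me
    of in on at by for with to from as into onto over under between
    among within without about against after before above below up down
    out off per via than
    and or but nor not no neither either both each such including
    is are was were be been being am
    has have had having do does did done
    can will shall just should would could may might must
    if because until unless while during where when how what which who
    whom whose why
    also then there here only own same so too very more most some any
    other others all
    """.split()
)


def is_stop_word(token: str) -> bool:
    return token.lower() in STOP_WORDS
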