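"""Default English stop-list for the sentence-similarity path.

Applied only when preparing sentences for similarity scoring, never when
building the training corpus.  Deliberately small: function words and
high-frequency verbs that carry no topical signal in biomedical prose.
"""

DEFAULT_STOPWORDS = frozenset(
    """
    a an the this that these those there here
    i you he she it we they me him her us them its their his our your my
    am is are was were be been being
    do does did doing done have has had having
    will would shall should can could may might must
    and or but nor so yet if then else when while because although though
    as than such both either neither each every all any some no not only
    of in on at by for with from to into onto over under between among
    about against during before after above below up down out off through
    again further once more most other another same own just very too also
    what which who whom whose where why how
    """.split()
)
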