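# Negation trigger lexicon: PRE <phrase> | POST <phrase> | TERM <word>
# Entries are preprocessed (lowercased, lemmatized) on load.
PRE no
PRE not
PRE without
PRE denies
PRE denied
PRE deny
PRE negative for
PRE no evidence of
PRE no sign of
PRE rule out
PRE ruled out
PRE free of
PRE never
PRE absence of
POST unlikely
POST ruled out
POST rule out
POST resolved
TERM but
TERM however
TERM although
TERM though
TERM yet
TERM except
TERM aside
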