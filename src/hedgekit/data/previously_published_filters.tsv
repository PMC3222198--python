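# Previously published diagnosis filters (user-fillable).
# Their query strings are not shipped; add one filter per line as
# name<TAB>query string<TAB>provenance
# e.g.  Haynes-2004-Sensitive	<query string>	Haynes et al., 2004
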