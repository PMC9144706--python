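substance,cas,clp_class
benzene,71-43-2,1A
naphthalene,91-20-3,2
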