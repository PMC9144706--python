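substance,cas,iur_per_ug_m3
benzene,71-43-2,7.8e-6
naphthalene,91-20-3,3.4e-5
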