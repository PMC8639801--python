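category,prefix
chemotherapy,Z511
chemotherapy,Z512
organ_transplant,Z940
organ_transplant,Z941
organ_transplant,Z942
organ_transplant,Z943
organ_transplant,Z944
organ_transplant,Z948
rehabilitation,Z50
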