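name	accession	mass_da
14-3-3 protein sigma	1433S_HUMAN	3376.60
Thymosin beta-4	TYB4_HUMAN	4761.42
Thymosin beta-4	TYB4_HUMAN	4977.49
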