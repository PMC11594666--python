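name	fwd	rev
2O	ACTACTTATCTCTGCTGCTGCT	TAAGGTGTTTTCCTAGGTAGAA
5O	GGCCCAAACTCGGATGATTGGG	AACAGCAGCAGCAGCAGCAGCA
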