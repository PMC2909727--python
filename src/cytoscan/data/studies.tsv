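study	method	n_samples
Klatte09	GPG	246
Beroud96	qPCR	118
Gunawan01	G-Banding	118
Toma08	SNP10K	22
Yoshimoto07	BACPAC	26
Current	SNP100K	42
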