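mass_mz	weight	auc
2395	0.1311	0.80
4761	0.0693
4798	0.0553
4977	0.0667	0.81
6501	0.0249
6585	0.1204
6663	0.0774
7765	0.0358
7801	0.0273
8787	0.0537
12297	0.0245
15719	0.0298
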