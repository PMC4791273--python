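mass_mz	weight	auc
2434	0.0212
3008	0.0489
3334	0.0247
3376	0.0580	0.80
3448	0.0760
5150	0.0347
6203	0.0270
6663	0.0501	0.86
7017	0.0381
8581	0.0763	0.88
9274	0.0375
20804	0.0415
22238	0.0334
22533	0.0338
22738	0.0392
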