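sample_id	mz	intensity	snr	width
C_vulgaris_UTEX_395	2636	1000	10	8
C_vulgaris_UTEX_395	6030	1000	10	8
C_vulgaris_UTEX_395	6422	1000	10	8
C_vulgaris_UTEX_395	6451	1000	10	8
C_vulgaris_UTEX_395	10684	1000	10	8
S_acutus_LRB-AP_401	2712	1000	10	8
S_acutus_LRB-AP_401	2735	1000	10	8
C_sorokiniana_UTEX_1230	2908	1000	10	8
C_sorokiniana_UTEX_1230	4608	1000	10	8
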