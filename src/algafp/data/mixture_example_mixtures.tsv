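sample_id	mz	intensity	snr	width
Mixture_1	2636	1000	10	8
Mixture_1	2712	1000	10	8
Mixture_1	6030	1000	10	8
Mixture_1	6422	1000	10	8
Mixture_1	6451	1000	10	8
Mixture_1	6481	1000	10	8
Mixture_1	10684	1000	10	8
Mixture_1	11048	1000	10	8
Mixture_1	11230	1000	10	8
Mixture_2	2636	1000	10	8
Mixture_2	2712	1000	10	8
Mixture_2	2908	1000	10	8
Mixture_2	4608	1000	10	8
Mixture_2	6030	1000	10	8
Mixture_2	6422	1000	10	8
Mixture_2	6451	1000	10	8
Mixture_2	6481	1000	10	8
Mixture_2	10684	1000	10	8
Mixture_2	11048	1000	10	8
Mixture_2	11230	1000	10	8
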