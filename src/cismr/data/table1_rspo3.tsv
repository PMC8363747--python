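snp	effect_allele	other_allele	eaf	beta	se	or	ci_low	ci_high	pval	n	n_cases	n_controls	trait	trait_type
rs7741021	C	T	0.47	NA	NA	0.95	0.94	0.96	8.9E-65	NA	421084	737530	fracture_any_site	case_control
rs7741021	C	T	0.48	NA	NA	0.88	0.86	0.91	9.6E-14	NA	7324	431432	distal_forearm_fracture	case_control
rs7741021	C	T	0.48	NA	NA	0.94	0.90	0.98	4.4E-03	NA	4035	434902	hip_fracture	case_control
rs7741021	C	T	0.48	0.079	0.002	NA	NA	NA	5.6E-336	426824	NA	NA	ebmd	quantitative
rs7741021	C	T	0.48	0.088	0.028	NA	NA	NA	1.4E-03	2500	NA	NA	trabecular_vbmd	quantitative
rs7741021	C	T	0.48	-0.013	0.015	NA	NA	NA	4.1E-01	5878	NA	NA	cortical_vbmd	quantitative
rs7741021	C	T	0.48	0.012	0.017	NA	NA	NA	4.8E-01	5878	NA	NA	cortical_thickness	quantitative
rs7741021	C	T	0.44	0.15	NA	NA	NA	NA	2.4E-04	581	NA	NA	rspo3_mrna_adipose	quantitative
rs7741021	C	T	0.46	0.12	NA	NA	NA	NA	1.8E-04	483	NA	NA	rspo3_mrna_fibroblasts	quantitative
rs3734626	T	C	0.53	NA	NA	0.94	0.93	0.95	1.8E-20	NA	53184	426795	fracture_any_site	case_control
rs3734626	T	C	0.52	NA	NA	0.89	0.86	0.92	2.4E-12	NA	7324	431432	distal_forearm_fracture	case_control
rs3734626	T	C	0.52	NA	NA	0.95	0.91	0.99	1.4E-02	NA	4035	434902	hip_fracture	case_control
rs3734626	T	C	0.53	0.069	0.002	NA	NA	NA	1.9E-258	426824	NA	NA	ebmd	quantitative
rs3734626	T	C	0.51	0.092	0.028	NA	NA	NA	9.4E-04	2500	NA	NA	trabecular_vbmd	quantitative
rs3734626	T	C	0.52	-0.010	0.015	NA	NA	NA	5.0E-01	5878	NA	NA	cortical_vbmd	quantitative
rs3734626	T	C	0.52	0.015	0.017	NA	NA	NA	3.7E-01	5878	NA	NA	cortical_thickness	quantitative
rs3734626	T	C	0.56	0.325	0.023	NA	NA	NA	1.8E-45	3200	NA	NA	rspo3_circulating	quantitative
rs2489623	C	T	0.54	NA	NA	0.95	0.94	0.96	1.0E-14	NA	53184	426795	fracture_any_site	case_control
rs2489623	C	T	0.53	NA	NA	0.89	0.86	0.92	8.5E-13	NA	7324	431432	distal_forearm_fracture	case_control
rs2489623	C	T	0.53	NA	NA	0.96	0.92	1.01	1.1E-01	NA	4035	434902	hip_fracture	case_control
rs2489623	C	T	0.54	0.061	0.002	NA	NA	NA	6.6E-205	426824	NA	NA	ebmd	quantitative
rs2489623	C	T	0.53	0.084	0.028	NA	NA	NA	2.4E-03	2500	NA	NA	trabecular_vbmd	quantitative
rs2489623	C	T	0.53	0.020	0.015	NA	NA	NA	2.0E-01	5878	NA	NA	cortical_vbmd	quantitative
rs2489623	C	T	0.53	0.016	0.017	NA	NA	NA	3.5E-01	5878	NA	NA	cortical_thickness	quantitative
rs2489623	C	T	0.53	0.270	0.025	NA	NA	NA	3.6E-28	3301	NA	NA	rspo3_circulating	quantitative
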