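variable	kind	case_with	case_without	control_with	control_without	case_mean	case_sd	case_n	control_mean	control_sd	control_n	printed_p
age_years	continuous					76.0	5.7	26	76.4	4.8	19	0.79
smoking	categorical	2	24	2	17							1.0
vitamin_supplements	categorical	23	3	12	7							0.07
coronary_artery_disease	categorical	7	19	3	16							0.481
hypertension	categorical	17	9	11	8							0.757
hyperlipidemia	categorical	9	17	6	13							1.00
diabetes	categorical	0	26	0	19							1.00
cancer_history	categorical	3	23	1	18							0.627
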