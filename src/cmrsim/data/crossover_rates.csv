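metric,female,male,ratio_male_female
number_of_cos_analysed,500,3853,2
size_genetic_map_cm,332,575,
cos_per_cell,6.65,11.15,1.67
cos_per_chromosome_1_bivalent,1.63,2.85,1.75
cos_per_chromosome_1_bivalent_corrected,1.63,3.18,1.95
cos_per_chromosome_2_bivalent,1.19,1.89,1.58
cos_per_chromosome_3_bivalent,1.29,2.14,1.66
cos_per_chromosome_4_bivalent,1.10,1.71,1.56
cos_per_chromosome_5_bivalent,1.44,2.58,1.79
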