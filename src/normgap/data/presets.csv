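preset_id,male_share_total,female_adolescent_share,male_adolescent_share,adol_15_19_fraction,illustrative_fields
ZAMBIA,0.453,0.289,0.268,0.55,adol_15_19_fraction
MAI06,0.208,0.168,0.268,0.55,female_adolescent_share;male_adolescent_share;adol_15_19_fraction
HAI12,0.412,0.250,0.268,0.55,male_adolescent_share;adol_15_19_fraction
SEN10,0.296,0.050,0.268,0.55,male_share_total;male_adolescent_share;adol_15_19_fraction
LES09,0.296,0.168,0.420,0.55,male_share_total;female_adolescent_share;adol_15_19_fraction
MAI12,0.296,0.168,0.130,0.55,male_share_total;female_adolescent_share;adol_15_19_fraction
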