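tissue,system
spinal_cord,nervous
motor_cortex,nervous
cerebellum,nervous
whole_blood,haematologic/immune
bone_marrow,haematologic/immune
liver,digestive
colon,digestive
lung,respiratory
heart,circulatory
placenta,placenta
thyroid,endocrine
testis,genital
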