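label	hemisphere	lobe
lh_temporal_lobe	L	temporal
rh_temporal_lobe	R	temporal
lh_inferior_frontal_gyrus	L	frontal
rh_inferior_frontal_gyrus	R	frontal
lh_middle_frontal_gyrus	L	frontal
rh_middle_frontal_gyrus	R	frontal
lh_superior_frontal_gyrus	L	frontal
rh_superior_frontal_gyrus	R	frontal
lh_orbitofrontal_cortex	L	frontal
rh_orbitofrontal_cortex	R	frontal
lh_precentral_gyrus	L	frontal
rh_precentral_gyrus	R	frontal
lh_paracentral_lobule	L	frontal
rh_paracentral_lobule	R	frontal
lh_postcentral_gyrus	L	parietal
rh_postcentral_gyrus	R	parietal
lh_superior_parietal_lobule	L	parietal
rh_superior_parietal_lobule	R	parietal
lh_inferior_parietal_lobule	L	parietal
rh_inferior_parietal_lobule	R	parietal
lh_supramarginal_gyrus	L	parietal
rh_supramarginal_gyrus	R	parietal
lh_precuneus	L	parietal
rh_precuneus	R	parietal
lh_cuneus	L	occipital
rh_cuneus	R	occipital
lh_lateral_occipital_cortex	L	occipital
rh_lateral_occipital_cortex	R	occipital
lh_anterior_cingulate_gyrus	L	limbic/cingulate
rh_anterior_cingulate_gyrus	R	limbic/cingulate
lh_posterior_cingulate_gyrus	L	limbic/cingulate
rh_posterior_cingulate_gyrus	R	limbic/cingulate
lh_insula	L	insula
rh_insula	R	insula
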