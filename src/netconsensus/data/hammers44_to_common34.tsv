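hammers44	common34
lh_anterior_temporal_lobe_medial	lh_temporal_lobe
rh_anterior_temporal_lobe_medial	rh_temporal_lobe
lh_anterior_temporal_lobe_lateral	lh_temporal_lobe
rh_anterior_temporal_lobe_lateral	rh_temporal_lobe
lh_superior_temporal_gyrus	lh_temporal_lobe
rh_superior_temporal_gyrus	rh_temporal_lobe
lh_middle_and_inferior_temporal_gyrus	lh_temporal_lobe
rh_middle_and_inferior_temporal_gyrus	rh_temporal_lobe
lh_fusiform_gyrus	lh_temporal_lobe
rh_fusiform_gyrus	rh_temporal_lobe
lh_posterior_temporal_lobe	lh_temporal_lobe
rh_posterior_temporal_lobe	rh_temporal_lobe
lh_inferior_frontal_gyrus	lh_inferior_frontal_gyrus
rh_inferior_frontal_gyrus	rh_inferior_frontal_gyrus
lh_middle_frontal_gyrus	lh_middle_frontal_gyrus
rh_middle_frontal_gyrus	rh_middle_frontal_gyrus
lh_superior_frontal_gyrus	lh_superior_frontal_gyrus
rh_superior_frontal_gyrus	rh_superior_frontal_gyrus
lh_orbitofrontal_cortex	lh_orbitofrontal_cortex
rh_orbitofrontal_cortex	rh_orbitofrontal_cortex
lh_precentral_gyrus	lh_precentral_gyrus
rh_precentral_gyrus	rh_precentral_gyrus
lh_paracentral_lobule	lh_paracentral_lobule
rh_paracentral_lobule	rh_paracentral_lobule
lh_postcentral_gyrus	lh_postcentral_gyrus
rh_postcentral_gyrus	rh_postcentral_gyrus
lh_superior_parietal_lobule	lh_superior_parietal_lobule
rh_superior_parietal_lobule	rh_superior_parietal_lobule
lh_inferior_parietal_lobule	lh_inferior_parietal_lobule
rh_inferior_parietal_lobule	rh_inferior_parietal_lobule
lh_supramarginal_gyrus	lh_supramarginal_gyrus
rh_supramarginal_gyrus	rh_supramarginal_gyrus
lh_precuneus	lh_precuneus
rh_precuneus	rh_precuneus
lh_cuneus	lh_cuneus
rh_cuneus	rh_cuneus
lh_lateral_occipital_cortex	lh_lateral_occipital_cortex
rh_lateral_occipital_cortex	rh_lateral_occipital_cortex
lh_anterior_cingulate_gyrus	lh_anterior_cingulate_gyrus
rh_anterior_cingulate_gyrus	rh_anterior_cingulate_gyrus
lh_posterior_cingulate_gyrus	lh_posterior_cingulate_gyrus
rh_posterior_cingulate_gyrus	rh_posterior_cingulate_gyrus
lh_insula	lh_insula
rh_insula	rh_insula
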