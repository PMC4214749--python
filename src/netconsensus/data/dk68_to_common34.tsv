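dk68	common34
lh_bankssts	lh_temporal_lobe
rh_bankssts	rh_temporal_lobe
lh_entorhinal	lh_temporal_lobe
rh_entorhinal	rh_temporal_lobe
lh_fusiform	lh_temporal_lobe
rh_fusiform	rh_temporal_lobe
lh_inferiortemporal	lh_temporal_lobe
rh_inferiortemporal	rh_temporal_lobe
lh_middletemporal	lh_temporal_lobe
rh_middletemporal	rh_temporal_lobe
lh_parahippocampal	lh_temporal_lobe
rh_parahippocampal	rh_temporal_lobe
lh_superiortemporal	lh_temporal_lobe
rh_superiortemporal	rh_temporal_lobe
lh_temporalpole	lh_temporal_lobe
rh_temporalpole	rh_temporal_lobe
lh_transversetemporal	lh_temporal_lobe
rh_transversetemporal	rh_temporal_lobe
lh_parsopercularis	lh_inferior_frontal_gyrus
rh_parsopercularis	rh_inferior_frontal_gyrus
lh_parsorbitalis	lh_inferior_frontal_gyrus
rh_parsorbitalis	rh_inferior_frontal_gyrus
lh_parstriangularis	lh_inferior_frontal_gyrus
rh_parstriangularis	rh_inferior_frontal_gyrus
lh_caudalmiddlefrontal	lh_middle_frontal_gyrus
rh_caudalmiddlefrontal	rh_middle_frontal_gyrus
lh_rostralmiddlefrontal	lh_middle_frontal_gyrus
rh_rostralmiddlefrontal	rh_middle_frontal_gyrus
lh_superiorfrontal	lh_superior_frontal_gyrus
rh_superiorfrontal	rh_superior_frontal_gyrus
lh_frontalpole	lh_superior_frontal_gyrus
rh_frontalpole	rh_superior_frontal_gyrus
lh_lateralorbitofrontal	lh_orbitofrontal_cortex
rh_lateralorbitofrontal	rh_orbitofrontal_cortex
lh_medialorbitofrontal	lh_orbitofrontal_cortex
rh_medialorbitofrontal	rh_orbitofrontal_cortex
lh_precentral	lh_precentral_gyrus
rh_precentral	rh_precentral_gyrus
lh_paracentral	lh_paracentral_lobule
rh_paracentral	rh_paracentral_lobule
lh_postcentral	lh_postcentral_gyrus
rh_postcentral	rh_postcentral_gyrus
lh_superiorparietal	lh_superior_parietal_lobule
rh_superiorparietal	rh_superior_parietal_lobule
lh_inferiorparietal	lh_inferior_parietal_lobule
rh_inferiorparietal	rh_inferior_parietal_lobule
lh_supramarginal	lh_supramarginal_gyrus
rh_supramarginal	rh_supramarginal_gyrus
lh_precuneus	lh_precuneus
rh_precuneus	rh_precuneus
lh_cuneus	lh_cuneus
rh_cuneus	rh_cuneus
lh_pericalcarine	lh_cuneus
rh_pericalcarine	rh_cuneus
lh_lateraloccipital	lh_lateral_occipital_cortex
rh_lateraloccipital	rh_lateral_occipital_cortex
lh_lingual	lh_lateral_occipital_cortex
rh_lingual	rh_lateral_occipital_cortex
lh_caudalanteriorcingulate	lh_anterior_cingulate_gyrus
rh_caudalanteriorcingulate	rh_anterior_cingulate_gyrus
lh_rostralanteriorcingulate	lh_anterior_cingulate_gyrus
rh_rostralanteriorcingulate	rh_anterior_cingulate_gyrus
lh_posteriorcingulate	lh_posterior_cingulate_gyrus
rh_posteriorcingulate	rh_posterior_cingulate_gyrus
lh_isthmuscingulate	lh_posterior_cingulate_gyrus
rh_isthmuscingulate	rh_posterior_cingulate_gyrus
lh_insula	lh_insula
rh_insula	rh_insula
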