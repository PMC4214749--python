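label	hemisphere	lobe
lh_bankssts	L	temporal
rh_bankssts	R	temporal
lh_entorhinal	L	temporal
rh_entorhinal	R	temporal
lh_fusiform	L	temporal
rh_fusiform	R	temporal
lh_inferiortemporal	L	temporal
rh_inferiortemporal	R	temporal
lh_middletemporal	L	temporal
rh_middletemporal	R	temporal
lh_parahippocampal	L	temporal
rh_parahippocampal	R	temporal
lh_superiortemporal	L	temporal
rh_superiortemporal	R	temporal
lh_temporalpole	L	temporal
rh_temporalpole	R	temporal
lh_transversetemporal	L	temporal
rh_transversetemporal	R	temporal
lh_parsopercularis	L	frontal
rh_parsopercularis	R	frontal
lh_parsorbitalis	L	frontal
rh_parsorbitalis	R	frontal
lh_parstriangularis	L	frontal
rh_parstriangularis	R	frontal
lh_caudalmiddlefrontal	L	frontal
rh_caudalmiddlefrontal	R	frontal
lh_rostralmiddlefrontal	L	frontal
rh_rostralmiddlefrontal	R	frontal
lh_superiorfrontal	L	frontal
rh_superiorfrontal	R	frontal
lh_frontalpole	L	frontal
rh_frontalpole	R	frontal
lh_lateralorbitofrontal	L	frontal
rh_lateralorbitofrontal	R	frontal
lh_medialorbitofrontal	L	frontal
rh_medialorbitofrontal	R	frontal
lh_precentral	L	frontal
rh_precentral	R	frontal
lh_paracentral	L	frontal
rh_paracentral	R	frontal
lh_postcentral	L	parietal
rh_postcentral	R	parietal
lh_superiorparietal	L	parietal
rh_superiorparietal	R	parietal
lh_inferiorparietal	L	parietal
rh_inferiorparietal	R	parietal
lh_supramarginal	L	parietal
rh_supramarginal	R	parietal
lh_precuneus	L	parietal
rh_precuneus	R	parietal
lh_cuneus	L	occipital
rh_cuneus	R	occipital
lh_pericalcarine	L	occipital
rh_pericalcarine	R	occipital
lh_lateraloccipital	L	occipital
rh_lateraloccipital	R	occipital
lh_lingual	L	occipital
rh_lingual	R	occipital
lh_caudalanteriorcingulate	L	limbic/cingulate
rh_caudalanteriorcingulate	R	limbic/cingulate
lh_rostralanteriorcingulate	L	limbic/cingulate
rh_rostralanteriorcingulate	R	limbic/cingulate
lh_posteriorcingulate	L	limbic/cingulate
rh_posteriorcingulate	R	limbic/cingulate
lh_isthmuscingulate	L	limbic/cingulate
rh_isthmuscingulate	R	limbic/cingulate
lh_insula	L	insula
rh_insula	R	insula
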