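parcel	hemisphere	lobe
lh_bankssts	left	temporal
lh_caudalanteriorcingulate	left	cingulate
lh_caudalmiddlefrontal	left	frontal
lh_cuneus	left	occipital
lh_entorhinal	left	temporal
lh_frontalpole	left	frontal
lh_fusiform	left	temporal
lh_inferiorparietal	left	parietal
lh_inferiortemporal	left	temporal
lh_insula	left	unassigned
lh_isthmuscingulate	left	cingulate
lh_lateraloccipital	left	occipital
lh_lateralorbitofrontal	left	frontal
lh_lingual	left	occipital
lh_medialorbitofrontal	left	frontal
lh_middletemporal	left	temporal
lh_paracentral	left	frontal
lh_parahippocampal	left	temporal
lh_parsopercularis	left	frontal
lh_parsorbitalis	left	frontal
lh_parstriangularis	left	frontal
lh_pericalcarine	left	occipital
lh_postcentral	left	parietal
lh_posteriorcingulate	left	cingulate
lh_precentral	left	frontal
lh_precuneus	left	parietal
lh_rostralanteriorcingulate	left	cingulate
lh_rostralmiddlefrontal	left	frontal
lh_superiorfrontal	left	frontal
lh_superiorparietal	left	parietal
lh_superiortemporal	left	temporal
lh_supramarginal	left	parietal
lh_temporalpole	left	temporal
lh_transversetemporal	left	temporal
rh_bankssts	right	temporal
rh_caudalanteriorcingulate	right	cingulate
rh_caudalmiddlefrontal	right	frontal
rh_cuneus	right	occipital
rh_entorhinal	right	temporal
rh_frontalpole	right	frontal
rh_fusiform	right	temporal
rh_inferiorparietal	right	parietal
rh_inferiortemporal	right	temporal
rh_insula	right	unassigned
rh_isthmuscingulate	right	cingulate
rh_lateraloccipital	right	occipital
rh_lateralorbitofrontal	right	frontal
rh_lingual	right	occipital
rh_medialorbitofrontal	right	frontal
rh_middletemporal	right	temporal
rh_paracentral	right	frontal
rh_parahippocampal	right	temporal
rh_parsopercularis	right	frontal
rh_parsorbitalis	right	frontal
rh_parstriangularis	right	frontal
rh_pericalcarine	right	occipital
rh_postcentral	right	parietal
rh_posteriorcingulate	right	cingulate
rh_precentral	right	frontal
rh_precuneus	right	parietal
rh_rostralanteriorcingulate	right	cingulate
rh_rostralmiddlefrontal	right	frontal
rh_superiorfrontal	right	frontal
rh_superiorparietal	right	parietal
rh_superiortemporal	right	temporal
rh_supramarginal	right	parietal
rh_temporalpole	right	temporal
rh_transversetemporal	right	temporal
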