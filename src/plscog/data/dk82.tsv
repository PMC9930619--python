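label	hemisphere	lobe
lh_superiorfrontal	left	frontal
lh_rostralmiddlefrontal	left	frontal
lh_caudalmiddlefrontal	left	frontal
lh_parsopercularis	left	frontal
lh_parstriangularis	left	frontal
lh_parsorbitalis	left	frontal
lh_lateralorbitofrontal	left	frontal
lh_medialorbitofrontal	left	frontal
lh_precentral	left	frontal
lh_paracentral	left	frontal
lh_frontalpole	left	frontal
lh_rostralanteriorcingulate	left	frontal
lh_caudalanteriorcingulate	left	frontal
lh_superiorparietal	left	parietal
lh_inferiorparietal	left	parietal
lh_supramarginal	left	parietal
lh_postcentral	left	parietal
lh_precuneus	left	parietal
lh_posteriorcingulate	left	parietal
lh_isthmuscingulate	left	parietal
lh_lateraloccipital	left	occipital
lh_lingual	left	occipital
lh_cuneus	left	occipital
lh_pericalcarine	left	occipital
lh_thalamus	left	subcortical
lh_caudate	left	subcortical
lh_putamen	left	subcortical
lh_pallidum	left	subcortical
lh_hippocampus	left	subcortical
lh_amygdala	left	subcortical
lh_accumbens	left	subcortical
lh_insula	left	subcortical
lh_superiortemporal	left	temporal
lh_middletemporal	left	temporal
lh_inferiortemporal	left	temporal
lh_bankssts	left	temporal
lh_fusiform	left	temporal
lh_transversetemporal	left	temporal
lh_entorhinal	left	temporal
lh_temporalpole	left	temporal
lh_parahippocampal	left	temporal
rh_superiorfrontal	right	frontal
rh_rostralmiddlefrontal	right	frontal
rh_caudalmiddlefrontal	right	frontal
rh_parsopercularis	right	frontal
rh_parstriangularis	right	frontal
rh_parsorbitalis	right	frontal
rh_lateralorbitofrontal	right	frontal
rh_medialorbitofrontal	right	frontal
rh_precentral	right	frontal
rh_paracentral	right	frontal
rh_frontalpole	right	frontal
rh_rostralanteriorcingulate	right	frontal
rh_caudalanteriorcingulate	right	frontal
rh_superiorparietal	right	parietal
rh_inferiorparietal	right	parietal
rh_supramarginal	right	parietal
rh_postcentral	right	parietal
rh_precuneus	right	parietal
rh_posteriorcingulate	right	parietal
rh_isthmuscingulate	right	parietal
rh_lateraloccipital	right	occipital
rh_lingual	right	occipital
rh_cuneus	right	occipital
rh_pericalcarine	right	occipital
rh_thalamus	right	subcortical
rh_caudate	right	subcortical
rh_putamen	right	subcortical
rh_pallidum	right	subcortical
rh_hippocampus	right	subcortical
rh_amygdala	right	subcortical
rh_accumbens	right	subcortical
rh_insula	right	subcortical
rh_superiortemporal	right	temporal
rh_middletemporal	right	temporal
rh_inferiortemporal	right	temporal
rh_bankssts	right	temporal
rh_fusiform	right	temporal
rh_transversetemporal	right	temporal
rh_entorhinal	right	temporal
rh_temporalpole	right	temporal
rh_parahippocampal	right	temporal
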