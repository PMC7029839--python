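# Seven resting-state networks and their member regions.
# Every region is bilateral: the L_/R_ prefix distinguishes hemispheres.
# STM (striatum) must contain exactly the six basal-ganglia regions.
MTN:
  - L_precentral_gyrus
  - R_precentral_gyrus
  - L_supplementary_motor_area
  - R_supplementary_motor_area
  - L_postcentral_gyrus
  - R_postcentral_gyrus
  - L_precuneus
  - R_precuneus
  - L_paracentral_lobule
  - R_paracentral_lobule
DMN:
  - L_superior_frontal_gyrus_dorsolateral
  - R_superior_frontal_gyrus_dorsolateral
  - L_superior_frontal_gyrus_orbital
  - R_superior_frontal_gyrus_orbital
  - L_middle_frontal_gyrus_lateral
  - R_middle_frontal_gyrus_lateral
  - L_middle_frontal_gyrus_orbital
  - R_middle_frontal_gyrus_orbital
  - L_inferior_frontal_gyrus_opercular
  - R_inferior_frontal_gyrus_opercular
  - L_area_triangularis
  - R_area_triangularis
  - L_inferior_frontal_gyrus_orbital
  - R_inferior_frontal_gyrus_orbital
  - L_superior_frontal_gyrus_medial
  - R_superior_frontal_gyrus_medial
  - L_superior_frontal_gyrus_medial_orbital
  - R_superior_frontal_gyrus_medial_orbital
  - L_posterior_cingulate_gyrus
  - R_posterior_cingulate_gyrus
  - L_angular_gyrus
  - R_angular_gyrus
  - L_middle_temporal_gyrus
  - R_middle_temporal_gyrus
SAN:
  - L_rolandic_operculum
  - R_rolandic_operculum
  - L_insula
  - R_insula
  - L_anterior_cingulate_gyrus
  - R_anterior_cingulate_gyrus
  - L_middle_cingulate
  - R_middle_cingulate
  - L_parahippocampal_gyrus
  - R_parahippocampal_gyrus
  - L_amygdala
  - R_amygdala
STM:
  - L_caudate_nucleus
  - R_caudate_nucleus
  - L_putamen
  - R_putamen
  - L_globus_pallidus
  - R_globus_pallidus
TEP:
  - L_transverse_temporal_gyri
  - R_transverse_temporal_gyri
  - L_superior_temporal_gyrus
  - R_superior_temporal_gyrus
  - L_superior_temporal_pole
  - R_superior_temporal_pole
  - L_middle_temporal_pole
  - R_middle_temporal_pole
  - L_inferior_temporal_gyrus
  - R_inferior_temporal_gyrus
HIP:
  - L_hippocampus
  - R_hippocampus
DAN:
  - L_inferior_occipital
  - R_inferior_occipital
  - L_fusiform_gyrus
  - R_fusiform_gyrus
  - L_superior_parietal_lobule
  - R_superior_parietal_lobule
  - L_inferior_parietal_lobule
  - R_inferior_parietal_lobule
  - L_supramarginal_gyrus
  - R_supramarginal_gyrus
  - L_calcarine_sulcus
  - R_calcarine_sulcus
  - L_cuneus
  - R_cuneus
  - L_lingual_gyrus
  - R_lingual_gyrus
  - L_superior_occipital
  - R_superior_occipital
  - L_middle_occipital
  - R_middle_occipital
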