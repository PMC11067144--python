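# Composite VOI definitions over Desikan-Killiany parcel names.
#
# Thickness composites are surface-area-weighted means of member parcels per
# hemisphere (unweighted optional), volume composites are sums; both are then
# averaged across hemispheres.  Edit member lists freely; parcels must exist
# in the parsed stats tables.
vois:
  - name: temporal_meta_ct
    measure: thickness
    members: [entorhinal, parahippocampal, fusiform, inferiortemporal, middletemporal]
  - name: lateral_temporal_ct
    measure: thickness
    members: [superiortemporal, middletemporal, inferiortemporal, bankssts, transversetemporal]
  - name: lateral_parietal_ct
    measure: thickness
    members: [inferiorparietal, superiorparietal, supramarginal]
  - name: medial_parietal_ct
    measure: thickness
    members: [precuneus, posteriorcingulate, isthmuscingulate]
  - name: frontal_ct
    measure: thickness
    members:
      [superiorfrontal, rostralmiddlefrontal, caudalmiddlefrontal,
       parsopercularis, parstriangularis, parsorbitalis,
       lateralorbitofrontal, medialorbitofrontal, frontalpole]
  - name: hippocampus_vol
    measure: volume
    members: [Hippocampus]
  - name: amygdala_vol
    measure: volume
    members: [Amygdala]
  - name: entorhinal_vol
    measure: volume
    members: [entorhinal]
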