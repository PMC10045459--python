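# Full-analysis run on a synthetic season at the default study conditions.
# Replace the `simulate` block with
#   input: {records: records.csv, patches: patches.geojson}
# to analyse field data instead.
simulate:
  seed: 1
  # n_patches: 46
  # total_recruits: 5000
connectivity:
  alpha: null        # null -> 1 / mean observed dispersal distance (km)
  xi: 0.5
  buffer_km: 3.0
  distance_mode: centroid
cjs:
  min_individuals: 20
  min_transitions: 5
glmm:
  random: locality
out: runs/demo
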