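# Editable mapping from measurement field names to vocabulary concept ids.
# The ids below are placeholders in the local (>2e9) concept range; replace
# them with your site's standard concept ids before CDM loading.
field_name,concept_id,unit_concept_id
avg_rnfl_thickness,2000000001,2000000101
superior_rnfl_thickness,2000000002,2000000101
inferior_rnfl_thickness,2000000003,2000000101
total_macular_volume,2000000004,2000000102
central_macular_thickness,2000000005,2000000101
prev_total_macular_volume,2000000006,2000000102
prev_central_macular_thickness,2000000007,2000000101
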