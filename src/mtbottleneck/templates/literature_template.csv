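# Transcription template for published developmental mtDNA measurements.
# One row per published statistic:
#   source    - study label (free text; rows containing "mature" with no
#               t_dpc are assigned the 100 dpc mature-oocyte convention)
#   t_dpc     - days post conception of the measurement
#   statistic - copy_number_mean | normalised_het_variance
#   value     - the published value (normalised variance = V(h)/(E(h)(1-E(h))))
#   n         - number of cells/oocytes the statistic was computed from
# Rows with an empty value are placeholders and are skipped by the loader.
source,t_dpc,statistic,value,n
Cree,7.5,copy_number_mean,,
Cree,8.5,copy_number_mean,,
Cree,10.5,copy_number_mean,,
Cree,14.5,copy_number_mean,,
Cao,7.5,copy_number_mean,,
Cao,13.5,copy_number_mean,,
Wai,7.5,copy_number_mean,,
Wai,13.5,copy_number_mean,,
Wai_mature_oocyte,,copy_number_mean,,
Jenuth,7.5,normalised_het_variance,,
Jenuth,13.5,normalised_het_variance,,
Jenuth_mature_oocyte,,normalised_het_variance,,
Wai,7.5,normalised_het_variance,,
Wai,10.5,normalised_het_variance,,
Wai,13.5,normalised_het_variance,,
Wai,21.0,normalised_het_variance,,
HB,24.0,normalised_het_variance,,
HB,32.0,normalised_het_variance,,
HB,40.0,normalised_het_variance,,
HB,50.0,normalised_het_variance,,
HB,61.0,normalised_het_variance,,
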