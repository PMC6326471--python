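# Sensor parameter presets.
#
# huawei_p9_sec53:  Huawei P9 monochrome chip (Sony IMX286) at ISO 3200, from
#                   the photon-transfer calibration procedure (default preset).
# huawei_p9_table1: same chip with the alternative read-noise figure from the
#                   camera comparison table.
# emccd_ixon_table1: Andor iXon EM+ 897 reference camera; the conversion gain
#                   is not published in the comparison table, 1.0 e-/ADU is a
#                   nominal placeholder.

huawei_p9_sec53:
  gain: 0.69
  offset: 4.1
  read_noise: 2.5
  bit_depth: 12
  linear_max: 220
  qe: 0.75

huawei_p9_table1:
  gain: 0.69
  offset: 4.1
  read_noise: 1.23
  bit_depth: 12
  linear_max: 220
  qe: 0.75

emccd_ixon_table1:
  gain: 1.0
  offset: 100.0
  read_noise: 0.2
  bit_depth: 14
  linear_max: 16383
  qe: 0.9
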