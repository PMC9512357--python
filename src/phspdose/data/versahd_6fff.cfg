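# Versa HD 6 MV flattening-filter-free (FFF) beam model.
# Source 2 represents scatter from the primary collimator.

[machine]
quality = FFF
source_to_isocenter_mm = 1000.0
phase_plane_mm = 548.0
collimator_mm = 401.8
grid_size_i = 800
grid_size_j = 800
grid_resolution_x_mm = 0.5
grid_resolution_y_mm = 0.5
grid_edge_x_mm = -200.0
grid_edge_y_mm = -200.0
fixed_x_jaw_mm = 200.0
mlc_leaf_count = 160
mlc_leaf_width_mm = 5.0

[source.1]
position_mm = 0.0
weight = 0.96
sigma_x_mm = 2.0
sigma_y_mm = 0.5

[source.2]
position_mm = 150.0
weight = 0.04
sigma_x_mm = 24.0
sigma_y_mm = 24.0

[calibration]
particles_per_mu_mm2 = 2.18e-14
mlc_transmission = 0.0
cgy_per_unit = 7.398e12

[fluence_profile]
0.0    1.000
20.0   0.971
50.0   0.865
70.0   0.787
90.0   0.720
100.0  0.684
150.0  0.552
175.0  0.499
190.0  0.475
200.0  0.455
210.0  0.435
225.0  0.410
240.0  0.375
250.0  0.345
255.0  0.325
258.0  0.000

[spectrum]
0.50  0.08990
1.00  0.09820
1.50  0.06197
2.00  0.05149
2.50  0.04309
3.00  0.03776
3.50  0.03369
4.00  0.03032
5.00  0.02645
6.00  0.02408

[scatter_factors]
10.0   0.980
20.0   0.980
30.0   0.960
50.0   0.985
100.0  1.000
150.0  1.000
200.0  1.015
400.0  1.020
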