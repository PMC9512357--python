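# Versa HD 6 MV flattened beam model.
# Dual Gaussian-source virtual-source model; all aperture/grid coordinates
# are expressed at the isocenter plane, distances in mm from the nominal
# (target) source, +z toward the patient.

[machine]
quality = flattened
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
weight = 0.94
sigma_x_mm = 1.5
sigma_y_mm = 1.5

[source.2]
position_mm = 150.0
weight = 0.06
sigma_x_mm = 24.0
sigma_y_mm = 24.0

[calibration]
# Absolute fluence calibration (particles per MU mm^2, model units).
particles_per_mu_mm2 = 2.02e-14
mlc_transmission = 0.0
# Commissioning constant converting scaled engine output to cGy; fixed so
# that 100 MU of the 100 mm x 100 mm reference field gives ~100 cGy at D_max.
cgy_per_unit = 7.814e12

# Primary fluence profile: off-axis position (mm at isocenter), relative intensity.
[fluence_profile]
0.0    1.000
10.0   1.003
20.0   1.006
50.0   1.020
70.0   1.025
90.0   1.030
100.0  1.035
150.0  1.047
175.0  1.051
190.0  1.055
200.0  1.060
210.0  1.060
230.0  1.000
260.0  0.500
261.0  0.000
500.0  0.000

# Energy spectrum: energy (MeV), relative intensity.
[spectrum]
0.50  0.04184
1.00  0.07318
1.50  0.08604
2.00  0.07853
2.50  0.06149
3.00  0.05403
3.50  0.03800
4.00  0.02962
5.00  0.02559
6.00  0.01542

# Collimator scatter factors: square field width (mm), factor (1.000 at 100 mm).
[scatter_factors]
10.0   0.970
20.0   0.930
30.0   0.940
50.0   0.975
100.0  1.000
150.0  1.015
200.0  1.030
400.0  1.040
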