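# BioMag 1 instrument preset: three mutually tangent saturable-core
# electromagnets under a 3 L (16 cm diameter) vessel, with the sizing inputs
# and identified control-loop parameters of the built device.
name = "biomag1"

[array]
n_electromagnets = 3
# centre-to-centre spacing of mutually tangent 5 cm coils
spacing_cm = 10.0

[electromagnet.winding]
inner_radius_cm = 5.0
height_cm = 4.0
turns = 300
# effective (enamelled) 20 AWG diameter; sets turn and layer pitch
wire_diameter_mm = 0.9
# 10 A total shared by three parallel coils
current_per_coil_a = 3.3333333333333335

[electromagnet.core]
radius_cm = 5.0            # stacked ASTM A36 discs
height_cm = 4.0
mu_r = 200.0
b_sat_t = 2.16

[sizing.wire]
awg = 20
mass_lb = 0.33333333333333331
current_a = 10.0
v_max_v = 15.0

[sizing.heater]
mass_g = 2500.0
cp_j_per_g_k = 4.1806
t_initial_c = 25.0
t_final_c = 50.0
heating_time_s = 300.0

[sizing.mixing]
fluid_density_kg_m3 = 1000.0
dynamic_viscosity_pa_s = 0.001
impeller_diameter_cm = 10.0
speed_rpm = 100.0
power_number = 5.0

[control.temperature]
gain_c_per_v = 1.475
time_constant_s = 990.0
dead_time_s = 120.0
ambient_c = 25.0
kp = 3.3
ki = 0.0033
kd = 82.5
v_line_v = 120.0
duty_period_s = 5.0
pid_activation_fraction = 0.2
tolerance_band_c = 1.0

[control.ph]
volume_l = 3.0
acid_mol_per_l = 0.47
base_mol_per_l = 0.5
drop_volume_ul = 50.0
pulse_s = 3.0
drop_rate_per_s = 1.0
settle_s = 5.0
noise_sd_ph = 0.05
filter_window = 5

[control.stirrer]
gain_rpm = 130.0
time_constant_s = 0.3
kp = 0.18
ki = 0.8
kd = 0.0016
noise_sd_rpm = 2.0
filter_window = 5
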