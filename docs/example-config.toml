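# Example hardware configuration for `photopath --config`.
# Every key is optional; omitted keys default to the reference device.

wavelength_nm = 405.0
led_offset_mm = 10.6          # mechanical couple-to-needle distance, mm
spot_center_offset_mm = 3.0   # spot centre offset toward the active azimuth, mm
slider_distance_mm = 15.0     # LED-substrate distance, in [1, 15] mm
couple_power_mW = 60.0        # one couple = two 30 mW LEDs in parallel
couple_azimuths = [0.0, 90.0, 180.0, 270.0]
code_map = [1, 2, 3, 4, 5, 6, 7, 8]  # sector k -> M102 code, device wiring
needle_radius_mm = 0.0

# resin working-curve parameters (5% w/v GelMA + 0.5% w/v LAP)
D_p = 0.61                    # penetration depth, mm
E_c = 0.48                    # critical energy, mJ/mm^2
# kappa = 1.3969              # exposure prefactor; default is calibrated
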