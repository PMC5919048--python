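# Double-exponential coefficient families Ec(n), A(n) for HeLa-cell Peleg-Fermi
# survival, one row per pulse length. Amplitudes are in kV/cm; rates are the
# complete signed exponents applied as amp*exp(rate*n).
pulse_length_us,ec_amp1,ec_rate1,ec_amp2,ec_rate2,ec_r_squared,a_amp1,a_rate1,a_amp2,a_rate2,a_r_squared
25,38.310,-0.2953,1.280,-0.001815,1.00,0.4442,-0.02095,11.0300,-0.73010,0.9996
50,24.910,-0.4257,2.250,-0.015030,1.00,0.2916,-0.01354,8.4900,-1.10700,0.9903
75,19.040,-0.3533,1.678,-0.010530,1.00,3.8130,-0.54730,0.2533,-0.01314,0.9998
100,8.428,-0.2237,1.038,-0.003552,1.00,1.0790,-0.33910,0.1678,-0.01329,0.9999
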