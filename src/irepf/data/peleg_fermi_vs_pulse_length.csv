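# Double-exponential coefficient families Ec(t), A(t) for HeLa-cell Peleg-Fermi
# survival, one row per pulse count. Amplitudes are in kV/cm; rates are the
# complete signed exponents applied as amp*exp(rate*t), t in microseconds.
pulse_count,ec_amp1,ec_rate1,ec_amp2,ec_rate2,ec_r_squared,a_amp1,a_rate1,a_amp2,a_rate2,a_r_squared
1,44.3000,-0.01620,0,0,0.9760,9.6030,-0.02092,0,0,0.9709
10,11.7700,-0.10880,2.6520,-0.00323,1.0000,1.0010,-0.07780,0.2776,-0.003821,0.9847
30,12.9700,-0.01840,-12.4900,-0.02421,1.0000,3.1940,-0.02519,-3.4880,-0.032750,0.9681
60,0.9476,-0.08218,0.9599,-0.00128,1.0000,0.2557,-0.05917,0.1441,-0.006390,0.9800
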