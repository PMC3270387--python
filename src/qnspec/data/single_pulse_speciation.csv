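sample,tau_hours,species,delta_ppm,fwhm_ppm,fraction_pct,sd_pct,mode
S90,0,Q4,-109.8,10.7,67.4,,single_pulse
S90,0,Q3_H,-100.3,9.5,23.0,,single_pulse
S90,0,Q2_H,-91.0,10.0,5.9,,single_pulse
S90,0,Q2_Ca,-82.5,8.9,2.5,,single_pulse
S90,0,Q1_Ca,-74.0,10.0,1.2,,single_pulse
S90,0.5,Q4,-110.2,9.8,67.5,,single_pulse
S90,0.5,Q3_H,-100.4,8.3,23.1,,single_pulse
S90,0.5,Q2_H,-91.2,10.0,7.0,,single_pulse
S90,0.5,Q2_Ca,-82.5,7.6,1.4,,single_pulse
S90,0.5,Q1_Ca,-75.0,6.9,1.0,,single_pulse
S90,4,Q4,-110.2,9.5,69.5,,single_pulse
S90,4,Q3_H,-100.1,8.2,24.8,,single_pulse
S90,4,Q2_H,-91.1,6.9,4.6,,single_pulse
S90,4,Q2_Ca,-83.3,5.0,1.1,,single_pulse
S90,24,Q4,-110.7,9.3,72.9,,single_pulse
S90,24,Q3_H,-100.7,7.9,24.1,,single_pulse
S90,24,Q2_H,-91.5,7.5,3.0,,single_pulse
S90,72,Q4,-110.8,9.1,73.2,,single_pulse
S90,72,Q3_H,-100.9,8.0,24.4,,single_pulse
S90,72,Q2_H,-91.3,6.0,2.4,,single_pulse
S90,168,Q4,-110.8,9.0,74.2,,single_pulse
S90,168,Q3_H,-101.0,7.9,23.5,,single_pulse
S90,168,Q2_H,-91.5,7.9,2.3,,single_pulse
S85,0,Q4,-109.7,11.2,75.1,,single_pulse
S85,0,Q3_H,-100.2,8.5,17.8,,single_pulse
S85,0,Q2_H,-92.2,12.0,7.1,,single_pulse
S85,0.5,Q4,-110.5,10.2,75.1,,single_pulse
S85,0.5,Q3_H,-100.8,7.1,17.9,,single_pulse
S85,0.5,Q2_H,-93.9,12.0,7.0,,single_pulse
S85,1,Q4,-109.6,9.7,75.3,,single_pulse
S85,1,Q3_H,-100.0,7.4,21.1,,single_pulse
S85,1,Q2_H,-92.0,8.0,3.6,,single_pulse
S85,4,Q4,-110.9,9.3,72.0,,single_pulse
S85,4,Q3_H,-101.4,7.8,24.4,,single_pulse
S85,4,Q2_H,-93.0,7.9,3.6,,single_pulse
S85,24,Q4,-110.9,9.1,72.8,,single_pulse
S85,24,Q3_H,-101.3,7.8,23.8,,single_pulse
S85,24,Q2_H,-91.9,7.3,3.4,,single_pulse
S85,72,Q4,-111.1,9.0,72.6,,single_pulse
S85,72,Q3_H,-101.5,7.3,23.8,,single_pulse
S85,72,Q2_H,-93.0,8.8,3.6,,single_pulse
S85,168,Q4,-111.0,9.1,76.0,,single_pulse
S85,168,Q3_H,-101.3,7.3,21.1,,single_pulse
S85,168,Q2_H,-93.0,8.8,2.9,,single_pulse
S58,0,Q4,-108.8,11.8,44.6,,single_pulse
S58,0,Q3_H,-99.3,8.3,18.3,,single_pulse
S58,0,Q2H_Q3Ca,-91.5,10.5,18.2,,single_pulse
S58,0,Q2_Ca,-83.0,9.3,13.5,,single_pulse
S58,0,Q1_Ca,-76.0,8.4,5.4,,single_pulse
S58,168,Q4,-110.3,10.5,45.0,,single_pulse
S58,168,Q3_H,-99.4,9.0,24.7,,single_pulse
S58,168,Q2H_Q3Ca,-91.4,10.5,17.4,,single_pulse
S58,168,Q2_Ca,-83.0,10.0,10.4,,single_pulse
S58,168,Q1_Ca,-74.2,9.5,2.5,,single_pulse
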