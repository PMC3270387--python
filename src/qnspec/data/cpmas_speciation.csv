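sample,tau_hours,species,delta_ppm,fwhm_ppm,fraction_pct,sd_pct,mode
S90,0,Q4,-109.5,10.7,24.0,,cpmas
S90,0,Q3_H,-100.1,8.1,52.1,,cpmas
S90,0,Q2_H,-91.2,7.0,14.3,,cpmas
S90,0,Q2_Ca,-83.5,10.0,7.3,,cpmas
S90,0,Q1_Ca,-76.3,9.8,2.3,,cpmas
S90,0.5,Q4,-109.9,10.0,26.3,,cpmas
S90,0.5,Q3_H,-100.3,7.3,52.3,,cpmas
S90,0.5,Q2_H,-91.8,8.8,16.4,,cpmas
S90,0.5,Q2_Ca,-82.7,8.0,4.1,,cpmas
S90,0.5,Q1_Ca,-76.0,5.1,0.9,,cpmas
S90,4,Q4,-110.0,9.7,26.8,,cpmas
S90,4,Q3_H,-100.5,7.1,53.8,,cpmas
S90,4,Q2_H,-92.6,9.6,16.5,,cpmas
S90,4,Q2_Ca,-83.0,11.0,2.4,,cpmas
S90,4,Q1_Ca,-76.0,12.0,0.5,,cpmas
S90,24,Q4,-110.3,9.4,25.4,,cpmas
S90,24,Q3_H,-100.7,7.1,58.4,,cpmas
S90,24,Q2_H,-92.4,8.8,14.9,,cpmas
S90,24,Q2_Ca,-83.3,5.1,1.3,,cpmas
S90,72,Q4,-110.6,9.1,26.4,,cpmas
S90,72,Q3_H,-100.8,6.7,59.6,,cpmas
S90,72,Q2_H,-92.9,9.7,14.0,,cpmas
S90,168,Q4,-110.7,8.9,28.1,,cpmas
S90,168,Q3_H,-100.9,6.5,60.8,,cpmas
S90,168,Q2_H,-92.7,8.9,11.1,,cpmas
S85,0,Q4,-109.4,11.7,24.5,,cpmas
S85,0,Q3_H,-100.2,7.9,55.5,,cpmas
S85,0,Q2_H,-91.1,6.8,14.9,,cpmas
S85,0,Q2_Ca,-83.0,11.6,5.1,,cpmas
S85,0.5,Q4,-110.3,9.8,27.3,,cpmas
S85,0.5,Q3_H,-100.6,7.2,56.3,,cpmas
S85,0.5,Q2_H,-92.2,8.1,13.5,,cpmas
S85,0.5,Q2_Ca,-82.0,12.0,2.9,,cpmas
S85,1,Q4,-110.5,9.7,29.9,,cpmas
S85,1,Q3_H,-100.7,7.1,55.9,,cpmas
S85,1,Q2_H,-92.4,8.1,12.5,,cpmas
S85,1,Q2_Ca,-83.0,10.3,1.7,,cpmas
S85,4,Q4,-110.4,9.8,26.9,,cpmas
S85,4,Q3_H,-100.7,6.9,57.6,,cpmas
S85,4,Q2_H,-92.6,8.9,14.5,,cpmas
S85,4,Q2_Ca,-83.0,5.0,0.8,,cpmas
S85,24,Q4,-110.8,9.2,28.0,,cpmas
S85,24,Q3_H,-100.9,6.8,60.6,,cpmas
S85,24,Q2_H,-92.3,8.0,11.0,,cpmas
S85,24,Q2_Ca,-82.0,5.1,0.4,,cpmas
S85,72,Q4,-110.9,8.9,25.0,,cpmas
S85,72,Q3_H,-101.0,6.7,62.7,,cpmas
S85,72,Q2_H,-92.4,8.1,12.3,,cpmas
S85,168,Q4,-111.1,9.1,27.6,,cpmas
S85,168,Q3_H,-101.0,6.8,63.0,,cpmas
S85,168,Q2_H,-92.3,7.5,9.4,,cpmas
S58,0,Q4,-108.7,10.1,15.6,,cpmas
S58,0,Q3_H,-99.5,8.3,39.0,,cpmas
S58,0,Q2H_Q3Ca,-90.7,8.2,22.1,,cpmas
S58,0,Q2_Ca,-83.5,8.2,15.1,,cpmas
S58,0,Q1_Ca,-77.0,8.2,8.2,,cpmas
S58,1,Q4,-109.3,9.2,15.6,,cpmas
S58,1,Q3_H,-100.2,7.0,34.5,,cpmas
S58,1,Q2H_Q3Ca,-91.5,10.7,27.9,,cpmas
S58,1,Q2_Ca,-83.0,10.5,16.2,,cpmas
S58,1,Q1_Ca,-77.0,9.6,5.8,,cpmas
S58,4,Q4,-109.7,8.8,14.6,,cpmas
S58,4,Q3_H,-100.4,7.0,36.9,,cpmas
S58,4,Q2H_Q3Ca,-91.7,10.5,26.6,,cpmas
S58,4,Q2_Ca,-82.8,10.5,17.6,,cpmas
S58,4,Q1_Ca,-76.1,8.7,4.3,,cpmas
S58,24,Q4,-109.6,9.5,17.2,,cpmas
S58,24,Q3_H,-100.6,7.0,34.1,,cpmas
S58,24,Q2H_Q3Ca,-92.0,10.5,26.3,,cpmas
S58,24,Q2_Ca,-83.5,10.0,17.2,,cpmas
S58,24,Q1_Ca,-76.7,8.1,5.2,,cpmas
S58,72,Q4,-110.1,8.7,15.1,,cpmas
S58,72,Q3_H,-100.5,7.5,34.1,,cpmas
S58,72,Q2H_Q3Ca,-91.5,10.5,26.9,,cpmas
S58,72,Q2_Ca,-83.0,10.1,19.2,,cpmas
S58,72,Q1_Ca,-76.0,8.1,4.7,,cpmas
S58,168,Q4,-109.9,9.0,15.0,,cpmas
S58,168,Q3_H,-100.2,8.2,31.5,,cpmas
S58,168,Q2H_Q3Ca,-91.5,10.5,26.8,,cpmas
S58,168,Q2_Ca,-83.5,10.4,20.6,,cpmas
S58,168,Q1_Ca,-76.6,8.8,6.1,,cpmas
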