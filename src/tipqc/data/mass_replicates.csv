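steps,mean,std,cv_printed
40,5.28,0.26,4.9
80,11.46,0.34,2.9
120,18.66,0.94,5.0
160,25.80,0.82,3.2
200,32.80,1.04,3.2
240,39.94,2.28,5.7
280,49.54,1.50,3.0
320,56.08,2.04,3.6
360,63.68,1.69,2.7
400,70.70,1.32,1.9
440,77.64,2.09,2.7
480,85.52,1.27,1.5
520,93.48,0.41,0.4
560,100.98,2.00,2.0
600,107.14,2.38,2.2
640,113.72,2.51,2.2
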