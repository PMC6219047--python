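steps,mean,std,cv_printed
40,72,1.87,2.6
80,101.6,0.55,0.5
120,126.8,1.30,1.0
160,143.8,2.28,1.6
200,159.6,2.79,1.7
240,173.6,5.32,3.1
280,189.2,2.49,1.3
320,198.4,3.05,1.5
360,209.6,2.19,1.0
400,218.8,2.49,1.1
440,226.8,2.59,1.1
480,234.2,2.95,1.3
520,244.6,0.89,0.4
560,251.2,1.30,0.5
600,256.8,1.79,0.7
640,259.2,2.17,0.8
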