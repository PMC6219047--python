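steps,dev,rel_dev_printed
40,25.3,63.2
80,7.5,9.4
120,1.9,1.5
160,9.9,6.2
200,14.4,7.2
240,20.1,8.4
280,8.6,3.1
320,14.3,4.5
360,9.2,2.6
400,10.8,2.7
440,12.0,2.7
480,14.7,3.1
520,16.1,3.1
560,17.1,3.1
600,15.3,2.6
640,18.3,2.9
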