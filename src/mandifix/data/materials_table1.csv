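name,E1,E2,E3,nu12,nu23,nu13,G12,G23,G13,yield_strength,isotropic
symphysis,20492,16350,12092,0.34,0.22,0.43,6908,4825,5317,,0
body,21728,17828,12700,0.34,0.20,0.45,7450,5083,5533,,0
angle,23793,19014,12757,0.30,0.22,0.41,7579,4986,5493,,0
ramus,24607,18357,12971,0.28,0.23,0.38,7407,5014,5386,,0
condyle,23500,17850,12650,0.24,0.25,0.32,7150,5150,5500,,0
coronoid_process,28000,17500,14000,0.23,0.28,0.28,7150,5300,5750,,0
trabecular,300,300,300,0.3,0.3,0.3,,,,,1
teeth,17600,17600,17600,0.34,0.34,0.34,6567,6567,6567,,1
granulation,3,3,3,0.4,0.4,0.4,1,1,1,,1
Ti-6Al-4V,110000,110000,110000,0.34,0.34,0.34,41045,41045,41045,880,1
WE43,44200,44200,44200,0.27,0.27,0.27,17000,17000,17000,162,1
PLA,3500,3500,3500,0.36,0.36,0.36,1287,1287,1287,70,1
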