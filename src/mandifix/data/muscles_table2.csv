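name,max_force,postop_force,cos_x_right,cos_x_left,cos_y,cos_z,activation_working,activation_balancing
SM,190.4,38.08,-0.207,0.207,-0.419,0.884,0.72,0.60
DM,81.6,16.32,-0.546,0.546,0.358,0.758,0.72,0.60
AT,158.0,31.6,-0.149,0.149,-0.044,0.988,0.73,0.58
MT,95.6,19.12,-0.222,0.222,0.500,0.837,0.66,0.67
PT,75.6,15.12,-0.208,0.208,0.855,0.474,0.59,0.39
MPt,174.8,34.96,0.486,-0.486,-0.373,0.791,0.84,0.60
LPt,66.9,13.38,0.630,-0.630,-0.757,-0.174,0.30,0.65
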