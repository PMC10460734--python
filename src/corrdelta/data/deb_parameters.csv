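name,value,units,cv1_percent,cv2_percent
mu_u,13.321,-,5,50
g_u,10.607,-,5,50
m_u,1.459e-2,1/day,30,80
delta_Vmax,4.146e-2,cm3/day,20,60
Vu10,1.160e-3,g,20,60
W0,22.263,g,2,5
Rb,7.310e-2,-,20,80
IVu50,5.300,cm3,10,60
k1,0.381,1/day,30,80
k2,0.129,ml/ng day,20,40
IC50,2.530e-2,ng/ml,10,60
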