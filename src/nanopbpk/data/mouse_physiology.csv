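organ,parameter,value,units
lung,Q,600.0,mL/h
lung,V_vasc,0.30,mL
lung,V_extra,0.10,mL
liver,Q,90.0,mL/h
liver,V_vasc,0.25,mL
liver,V_extra,1.10,mL
spleen,Q,7.0,mL/h
spleen,V_vasc,0.02,mL
spleen,V_extra,0.07,mL
kidney,Q,55.0,mL/h
kidney,V_vasc,0.10,mL
kidney,V_extra,0.32,mL
heart,Q,40.0,mL/h
heart,V_vasc,0.025,mL
heart,V_extra,0.11,mL
bone,Q,65.0,mL/h
bone,V_vasc,0.10,mL
bone,V_extra,2.40,mL
brain,Q,20.0,mL/h
brain,V_vasc,0.012,mL
brain,V_extra,0.42,mL
other,Q,323.0,mL/h
other,V_vasc,0.35,mL
other,V_extra,16.0,mL
blood,V_art,0.35,mL
blood,V_ven,0.70,mL
blood,cardiac_output,600.0,mL/h
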