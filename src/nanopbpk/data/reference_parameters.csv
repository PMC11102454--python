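organ,parameter,value,units
lung,PA,0.01,mL/h
lung,P,0.15,dimensionless
lung,K_max,0.02,1/h
lung,K_50,24.0,h
lung,n_H,1.0,dimensionless
lung,K_rel,0.05,1/h
lung,K_elim,0.0,mL/h
liver,PA,0.4,mL/h
liver,P,0.2,dimensionless
liver,K_max,0.25,1/h
liver,K_50,0.01,h
liver,n_H,1.0,dimensionless
liver,K_rel,0.05,1/h
liver,K_elim,0.1,mL/h
spleen,PA,0.2,mL/h
spleen,P,0.3,dimensionless
spleen,K_max,0.3,1/h
spleen,K_50,0.01,h
spleen,n_H,1.0,dimensionless
spleen,K_rel,0.5,1/h
spleen,K_elim,0.0,mL/h
kidney,PA,0.1,mL/h
kidney,P,0.15,dimensionless
kidney,K_max,0.8,1/h
kidney,K_50,125.0,h
kidney,n_H,1.0,dimensionless
kidney,K_rel,1.0,1/h
kidney,K_elim,0.0,mL/h
heart,PA,0.003,mL/h
heart,P,0.15,dimensionless
heart,K_max,0.0,1/h
heart,K_50,0.0,h
heart,n_H,1.0,dimensionless
heart,K_rel,0.0,1/h
heart,K_elim,0.0,mL/h
bone,PA,0.015,mL/h
bone,P,0.3,dimensionless
bone,K_max,0.0,1/h
bone,K_50,0.0,h
bone,n_H,1.0,dimensionless
bone,K_rel,0.0,1/h
bone,K_elim,0.0,mL/h
brain,PA,0.0001,mL/h
brain,P,0.15,dimensionless
brain,K_max,0.0,1/h
brain,K_50,0.0,h
brain,n_H,1.0,dimensionless
brain,K_rel,0.0,1/h
brain,K_elim,0.0,mL/h
other,PA,0.003,mL/h
other,P,0.2,dimensionless
other,K_max,0.0,1/h
other,K_50,0.0,h
other,n_H,1.0,dimensionless
other,K_rel,0.0,1/h
other,K_elim,0.0,mL/h
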