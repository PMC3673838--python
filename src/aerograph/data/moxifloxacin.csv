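id,label,phase,year,seq,outcome,status,children,same_report_children
u1,Ji et al. 1998,in_vitro,1998,0,positive,completed,,v1
v1,Ji et al. 1998,in_vivo,1998,0,positive,completed,v2,
u2,Gillespie et al. 1999,in_vitro,1999,0,positive,completed,w1;w2,
v2,Miyazaki et al. 1999,in_vivo,1999,0,positive,completed,v3;w1,
v3,Lounis et al. 2001,in_vivo,2001,0,positive,completed,v4,
v4,Yoshimatsu et al. 2002,in_vivo,2002,0,inconclusive,completed,v5,
w1,Gosling et al. 2003,phase1,2003,0,positive,completed,v5,
w2,Pletz et al. 2004,phase1,2004,0,positive,completed,v5,
v5,Nuermberger et al. 2004,in_vivo,2004,0,inconclusive,completed,u3;w3;w4,
w3,Gillespie et al. 2005,phase1,2005,0,negative,completed,x1,
w4,Johnson et al. 2006,phase1,2006,0,positive,completed,x1;x2,
x1,Burman et al. 2006,phase2,2006,0,negative,completed,w5;w6;x3;x4,
u3,Shandil et al. 2007,in_vitro,2007,0,positive,completed,w5;w6,
w5,Nijland et al. 2007,phase1,2007,0,negative,completed,,
x2,Rustomjee et al. 2007,phase2,2007,0,positive,completed,x3,
w6,Peloquin et al. 2008,phase1,2008,0,inconclusive,completed,x4,
x3,Conde et al. 2009,phase2,2009,0,positive,completed,x5,
x4,Dorman et al. 2009,phase2,2009,0,negative,completed,,
x5,Wang et al. 2009,phase2,2009,0,positive,completed,,
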