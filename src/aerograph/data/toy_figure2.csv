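id,label,phase,year,seq,outcome,status,children,same_report_children
α1,α1,in_vitro,2000,0,positive,completed,α2;β1,
α2,α2,in_vitro,2000,1,positive,completed,β2;β3,
β1,β1,in_vivo,2001,0,negative,completed,,
β2,β2,in_vivo,2002,0,positive,completed,γ1,
β3,β3,in_vivo,2002,1,positive,completed,γ2;γ3;δ2,
γ1,γ1,phase1,2003,0,positive,completed,δ1,
γ2,γ2,phase1,2003,1,inconclusive,completed,,
δ1,δ1,phase2,2004,0,negative,completed,γ3,
γ3,γ3,phase1,2004,1,positive,completed,δ2,
δ2,δ2,phase2,2005,0,positive,completed,,
δ3,δ3,phase2,2005,1,inconclusive,completed,,
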