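compound,atc_code,subgroup,zebrafish_detected,hipsc_detected
Bepridil,C08,Cardio,1,1
Dofetilide,C01,Cardio,1,1
Prenylamine,C01,Cardio,0,1
Probucol,C10,Cardio,1,0
Racepinephrine,C01,Cardio,1,1
Bromocriptine,N04,Neuro,1,1
Clozapine,N05,Neuro,1,1
Droperidol,N05,Neuro,1,1
Pergolide,N04,Neuro,0,0
Thioridazine,N05,Neuro,1,1
Astemizole,R06,Other,1,1
Celecoxib,M01,Other,1,0
Cisapride,A03,Other,1,1
Dexfenfluramine,A08,Other,1,0
Dolasetron,A04,Other,1,0
Metaproterenol,R03,Other,1,1
Rofecoxib,M01,Other,1,0
Sibutramine,A08,Other,1,1
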