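study_id,year,n,events,event_pct,settings,design,bias_score,duration_median_h,duration_iqr_lo_h,duration_iqr_hi_h,epi_n,norepi_n,dopa_n,dobu_n
Abrar,2022,369,8,2.2,PICU,prospective,9,24,13,1152,279,42,32,0
Charbel,2021,32,0,0.0,TRANSPORT,retrospective,8,3.8,2.7,4.5,3,32,0,7
Copana,2025,85,0,0.0,PICU,retrospective,9,,,,20,51,6,8
Kohn-Loncarica,2022,56,1,2.0,ER,prospective,7,1,0.8,2,40,12,1,3
Kumar,2015,204,3,1.5,PICU;ER,retrospective,9,,,,10,0,82,14
Lampin,2012,84,1,1.2,PICU,retrospective,7,3,2,4,0,84,,
Levy,2022,231,4,1.7,PICU,retrospective,7,3.4,2,8,30,43,189,0
Mooli,2021,84,3,3.6,ER;WARD,retrospective,9,12,1,72,41,60,4,6
Patregnani,2017,102,2,2.0,PICU;WARD;TRANSPORT,retrospective,6,4.3,2.4,9,25,11,85,0
Peshiman,2022,198,7,3.5,TRANSPORT,retrospective,9,3,1.8,5.3,119,20,88,0
Yeong,2022,65,0,0.0,ER,retrospective,9,2.4,1.5,4,23,6,47,7
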