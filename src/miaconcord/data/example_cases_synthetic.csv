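case_id,age_months,sex,postmortem_hours,mia_code,mia_chain,mia_underlying,mia_other,mia_path_level,mia_micro_level,mia_micro_concordant,mia_histo_org_inflam,mia_certainty,cda_code,cda_chain,cda_underlying,cda_other,cda_path_level,cda_micro_level,cda_micro_concordant,cda_histo_org_inflam,cda_certainty
P001,126.0,M,49.0,A41.5,A41.5,,,4,4,Y,N,very_high,A41.5,A41.5,,,2,2,Y,N,moderate
P002,127.0,M,46.0,A41.9,A41.9,,,3,0,,N,moderate,A41.9,A41.9,,,4,3,Y,N,very_high
P003,156.0,M,36.0,A40.1,A40.1,,,3,3,Y,N,high,A40.1,A40.1,,,1,1,N,N,low
P004,112.0,M,29.0,A40.3,A40.3,,,3,4,Y,N,very_high,A40.3,A40.3,,,3,4,Y,Y,very_high
P005,74.0,F,7.0,B50.0,B50.0,,,4,4,Y,N,very_high,B50.0,B50.0,,,4,3,Y,N,very_high
P006,119.0,M,19.0,B50.9,B50.9,,,4,2,Y,N,high,B50.9,B50.9,,,4,0,,N,high
P007,105.0,M,21.0,G00.1,G00.1,,,2,3,Y,Y,high,G00.1,G00.1,,,3,4,Y,N,very_high
P008,177.0,M,24.0,G00.0,G00.0,,,2,1,N,N,low,G00.0,G00.0,,,0,4,,N,moderate
P009,105.0,M,39.0,J13,J13,,,1,3,Y,N,moderate,J13,J13,,,3,4,Y,Y,very_high
P010,179.0,F,8.0,J14,J14,,,4,4,Y,N,very_high,J14,J14,,,4,3,Y,N,very_high
P011,167.0,M,54.0,J15.1,J15.1,,,3,4,Y,N,very_high,J15.1,J15.1,,,2,2,Y,N,moderate
P012,57.0,M,25.0,J18.9,J18.9,B20,,3,4,Y,Y,very_high,J18.9,J18.9,,,3,0,,N,moderate
P013,175.0,M,23.0,J18.0,J18.0,,,0,4,,N,moderate,J18.0,J18.0,,,4,4,Y,N,very_high
P014,172.0,F,23.0,A87.0,A87.0,,,1,2,N,N,low,A87.0,A87.0,,,1,1,N,N,low
P015,20.0,M,23.0,A17.0,A17.0,,,1,3,Y,N,moderate,A17.0,A17.0,,,3,3,Y,N,high
P016,83.0,M,32.0,A19.9,A19.9,,,4,3,Y,N,very_high,A19.9,A19.9,,,4,2,Y,N,high
P017,117.0,M,36.0,B45.1,B45.1,,,4,0,,N,high,B45.1,B45.1,,,3,4,Y,N,very_high
P018,169.0,F,14.0,A35,A35,,,2,3,Y,Y,high,A35,A35,,,3,3,Y,N,high
P019,41.0,F,11.0,A41.5,A41.5,,,2,2,Y,N,moderate,A41.9,A41.9,,,3,4,Y,Y,very_high
P020,112.0,F,24.0,J15.0,J15.0,,,4,4,Y,N,very_high,J15.9,J15.9,B20,,4,2,Y,N,high
P021,102.0,M,14.0,G00.1,G00.1,,,4,0,,N,high,G00.9,G00.9,,,3,0,,N,moderate
P022,85.0,F,5.0,B50.0,B50.0,,,0,4,,N,moderate,B50.8,B50.8,,,1,3,Y,N,moderate
P023,52.0,F,20.0,J18.0,J18.0,,,2,3,Y,Y,high,J18.9,J18.9,B20,,4,3,Y,N,very_high
P024,103.0,M,19.0,A17.0,A17.0,,,3,3,Y,N,high,A17.8,A17.8,,,3,4,Y,N,very_high
P025,32.0,F,19.0,A40.0,A40.0,,,4,2,Y,N,high,A41.9,A41.9,,,4,0,,N,high
P026,125.0,M,9.0,J15.5,J15.5,,,3,4,Y,Y,very_high,J18.9,J18.9,B20,,4,4,Y,N,very_high
P027,108.0,M,15.0,B50.9,B50.9,,,2,2,Y,N,moderate,B54,B54,,,4,3,Y,N,very_high
P028,76.0,M,41.0,A41.5,A41.5,,,2,1,N,N,low,A87.9,A87.9,,,3,0,,N,moderate
P029,173.0,M,18.0,J18.9,J18.9,B20,,3,4,Y,N,very_high,J21.9,J21.9,,,3,4,Y,Y,very_high
P030,173.0,M,10.0,B50.8,B50.8,,,0,4,,N,moderate,A41.9,A41.9,,,2,3,Y,Y,high
P031,172.0,M,6.0,J15.9,J15.9,B20,,3,3,Y,N,high,A41.5,A41.5,,,4,2,Y,N,high
P032,58.0,F,13.0,J18.9,J18.9,B20,,4,4,Y,N,very_high,A41.9,A41.9,,,4,3,Y,N,very_high
P033,16.0,M,51.0,J15.0,J15.0,,,1,3,Y,N,moderate,A49.9,A49.9,,,4,0,,N,high
P034,76.0,F,10.0,J18.0,J18.0,,,2,3,Y,Y,high,A85.8,A85.8,,,3,3,Y,N,high
P035,115.0,M,23.0,A41.5,A41.5,,,4,2,Y,N,high,J18.9,J18.9,B20,,3,4,Y,N,very_high
P036,57.0,M,9.0,J18.9,J18.9,B20,,4,0,,N,high,K65.0,K65.0,,,3,4,Y,Y,very_high
P037,70.0,M,33.0,J15.9,J15.9,,,2,2,Y,N,moderate,K65.9,K65.9,,,1,2,N,N,low
P038,91.0,M,46.0,A41.9,A41.9,,,4,4,Y,N,very_high,K65.0,K65.0,,,2,3,Y,Y,high
P039,128.0,M,27.0,J18.9,J18.9,B20,,4,3,Y,N,very_high,N10,N10,,,3,3,Y,N,high
P040,3.0,F,31.0,C83.7,C83.7,,,3,4,Y,N,very_high,C83.7,C83.7,,,3,4,Y,Y,very_high
P041,29.0,M,17.0,C83.7,C83.7,,,1,1,N,N,low,C83.7,C83.7,,,4,2,Y,N,high
P042,171.0,F,6.0,C83.7,C83.7,,,3,0,,N,moderate,C83.7,C83.7,,,4,0,,N,high
P043,141.0,M,52.0,C41.9,C41.9,,,4,4,Y,N,very_high,C41.9,C41.9,,,2,3,Y,Y,high
P044,46.0,M,24.0,C91.0,C91.0,,,3,3,Y,N,high,C91.0,C91.0,,,4,2,Y,N,high
P045,5.0,F,17.0,C41.2,C41.2,,,4,3,Y,N,very_high,C41.9,C41.9,,,4,0,,N,high
P046,167.0,M,7.0,C71.9,C71.9,,,2,3,Y,Y,high,C71.6,C71.6,,,3,3,Y,N,high
P047,86.0,M,55.0,I50.9,I50.9,,,4,2,Y,N,high,I50.9,I50.9,,,3,4,Y,N,very_high
P048,56.0,M,34.0,I61.9,I61.9,,,4,0,,N,high,I62.9,I62.9,,,2,3,Y,Y,high
P049,178.0,F,52.0,J18.9,J18.9,B20,,3,3,Y,N,high,Q21.0,Q21.0,,,3,4,Y,Y,very_high
P050,79.0,F,19.0,A41.9,A41.9,,,4,4,Y,N,very_high,Q24.9,Q24.9,,,4,2,Y,N,high
P051,79.0,M,5.0,J15.9,J15.9,B20,,4,0,,N,high,J84.9,J84.9,,,2,3,Y,Y,high
P052,23.0,M,36.0,I50.9,I50.9,,,4,3,Y,N,very_high,A41.5,A41.5,,,3,4,Y,N,very_high
P053,156.0,F,9.0,,,,,0,0,,N,no_diagnosis,A41.9,A41.9,,,3,4,Y,Y,very_high
P054,47.0,M,32.0,,,,,0,0,,N,no_diagnosis,J18.9,J18.9,B20,,3,3,Y,N,high
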