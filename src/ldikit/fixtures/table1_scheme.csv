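grade,node_id,parent_id,name,polarity,weight,data_year,note
1,1,,Health level,,0.327724212722882,,
1,2,,Medical capabilities,,0.149999991707872,,
1,3,,Disease prevention and control,,0.149999991530173,,
1,4,,Ecological environment,,0.094999992262849,,
1,5,,Health expenditure,,0.100000024509426,,
1,6,,Health industry,,0.180000007011142,,
2,1.1,1,Population situation,,,,
2,1.2,1,Health status,,,,
2,2.1,2,Institution,,,,
2,2.2,2,Personnel,,,,
2,2.3,2,Service,,,,
2,3.1,3,Prevention and control guarantee,,,,
2,3.2,3,Health education,,,,
2,4.1,4,Water quality,,,,
2,4.2,4,Air quality,,,,
2,4.3,4,Greening situation,,,,
2,4.4,4,Waste treatment,,,,
2,4.5,4,Natural calamities,,,,
2,4.6,4,Other related matters,,,,
2,5.1,5,Economic development,,,,
2,5.2,5,Medical expenses,,,,
2,5.3,5,Medical insurance,,,,
2,5.4,5,Birth insurance,,,,
2,5.5,5,Medical assistance,,,,
2,6.1,6,Health institution expenditure,,,,
2,6.2,6,Health product market,,,,
2,6.3,6,Pension industry,,,,
3,1.1.1,1.1,The proportion of population aged 0-14,1,0.415935301664094,2020,polarity assumed
3,1.1.2,1.1,The proportion of population aged 15-64,1,0.051971525168703,2020,polarity assumed
3,1.1.3,1.1,The proportion of population aged 65 and above,-1,0.000002334574056,2020,polarity assumed
3,1.1.4,1.1,Mortality,-1,0.000000035682448,2021,polarity assumed
3,1.1.5,1.1,Natural population growth rate,-1,0.000000103274644,2021,polarity assumed
3,1.2.1,1.2,Per capita life expectancy,1,0.415935331456722,2020,polarity assumed
3,1.2.2,1.2,System management rate for children under 3 years old,1,0.132744338799394,2021,polarity assumed
3,1.2.3,1.2,Maternal system management rate,1,0.131932745180370,2021,polarity assumed
3,1.2.4,1.2,Prenatal examination rate,1,0.239183524037821,2021,polarity assumed
3,2.1.1,2.1,"Number of comprehensive hospitals per 10,000 people",1,0.253278080123479,2021,polarity assumed
3,2.1.2,2.1,"Number of Traditional Chinese Medicine Hospitals per 10,000 People",1,0.000000008952145,2021,polarity assumed
3,2.1.3,2.1,"Number of specialized hospitals per 10,000 people",1,0.000000007270905,2021,polarity assumed
3,2.1.4,2.1,"Number of tertiary hospitals per 10,000 people",1,0.180000000839937,2021,polarity assumed
3,2.1.5,2.1,"Number of secondary hospitals per 10,000 people",1,0.093539539645429,2021,polarity assumed
3,2.1.6,2.1,"Number of primary hospitals per 10,000 people",1,0.176720074433797,2021,polarity assumed
3,2.1.7,2.1,"Number of primary healthcare institutions per 10,000 people",1,0.203491246713378,2021,polarity assumed
3,2.1.8,2.1,"Number of maternal and child health clinics/stations per 10,000 people",1,0.000000007091724,2021,polarity assumed
3,2.1.9,2.1,"Number of emergency centers per 10,000 people",1,0.082803337728690,2021,polarity assumed
3,2.1.10,2.1,"Number of sanatoriums per 10,000 people",1,0.116860529848141,2021,polarity assumed
3,2.1.11,2.1,Number of beds per thousand people in medical institutions,1,0.214355034991231,2021,polarity assumed
3,2.2.1,2.2,"Number of pharmacists per 10,000 people",1,0.000000002095553,2021,polarity assumed
3,2.2.2,2.2,"Number of technicians per 10,000 people",1,0.000000002455737,2021,polarity assumed
3,2.2.3,2.2,"Number of rural doctors and healthcare workers per 10,000 people",1,0.163487032251264,2021,polarity assumed
3,2.2.4,2.2,Number of health technicians per thousand people,1,0.000000002428709,2021,polarity assumed
3,2.2.5,2.2,Number of practicing (assistant) physicians per thousand people,1,0.123295108955931,2021,polarity assumed
3,2.2.6,2.2,Registered nurses per thousand people,1,0.000000040852497,2021,polarity assumed
3,2.3.1,2.3,Annual average number of visits by residents,1,0.068634495829494,2021,polarity assumed
3,2.3.2,2.3,Annual hospitalization rate of residents,1,0.000000025487552,2021,polarity assumed
3,2.3.3,2.3,Hospital bed utilization rate,1,0.000000002739868,2021,polarity assumed
3,2.3.4,2.3,Average length of hospital stay,-1,0.123295106779282,2021,polarity assumed
3,3.1.1,3.1,Incidence rate of Class A and B notifiable infectious diseases,-1,0.477229968505150,2021,polarity assumed
3,3.1.2,3.1,Class A and Class B statutory reported infectious disease mortality rate,-1,0.390205796288109,2021,polarity assumed
3,3.1.3,3.1,"Number of CDC personnel per 10,000 people",1,0.352819480989386,2021,polarity assumed
3,3.1.4,3.1,"Number of disease prevention and control centers per 10,000 people",1,0.000000576018228,2021,polarity assumed
3,3.1.5,3.1,Per capita annual health check ups,1,0.178032184107061,2021,polarity assumed
3,3.2.1,3.2,"Health education per 10,000 people (institution/station)",1,0.052833723115696,2021,polarity assumed
3,3.2.2,3.2,"Number of public health education activities per 10,000 people",1,0.062815763238227,2021,polarity assumed
3,4.1.1,4.1,Urban water supply penetration rate,1,0.000000052489771,2021,polarity assumed
3,4.1.2,4.1,The water quality compliance rate of centralized drinking water source areas in prefecture level and above cities,1,0.150000032826464,2021,polarity assumed
3,4.2.1,4.2,Days of good air quality in major cities,1,0.000000031315435,2021,polarity assumed
3,4.3.1,4.3,Urban per capita park green space area,1,0.179999081034425,2021,polarity assumed
3,4.3.2,4.3,Forest coverage rate,1,0.180000008339637,2021,polarity assumed
3,4.4.1,4.4,Urban sewage treatment rate,1,0.141410953036154,2021,polarity assumed
3,4.4.2,4.4,"Total emissions of major pollutants per 10,000 people",-1,0.083694479590853,2021,polarity assumed
3,4.4.3,4.4,Comprehensive utilization rate of general industrial solid waste,1,0.000000011634061,2021,polarity assumed
3,4.4.4,4.4,Harmless treatment rate of urban household waste,1,0.145312020303276,2021,polarity assumed
3,4.5.1,4.5,The proportion of natural disaster deaths to the total population,-1,0.045511448473591,2021,polarity assumed
3,4.5.2,4.5,The proportion of natural disaster victims to the total population,-1,0.000000004075498,2021,polarity assumed
3,4.6.1,4.6,Number of sudden environmental incidents,-1,0.073014973679382,2021,polarity assumed
3,4.6.2,4.6,Altitude,-1,0.130000040818452,2021,polarity assumed
3,5.1.1,5.1,Per capita regional gross domestic product,1,0.000000012571049,2021,polarity assumed
3,5.1.2,5.1,Per capita disposable income of residents,1,0.000000007146529,2021,polarity assumed
3,5.2.1,5.2,The proportion of total health expenses to GDP,1,0.149999977641731,2020,polarity assumed
3,5.2.2,5.2,Per capita total health expenses,1,0.400000003467838,2020,polarity assumed
3,5.2.3,5.2,The proportion of personal health expenditure to total health expenses,-1,0.000000005104950,2020,polarity assumed
3,5.3.1,5.3,"Basic medical insurance fund income per 10,000 people",1,0.000000006584571,2021,polarity assumed
3,5.4.1,5.4,The proportion of people enjoying maternity insurance benefits,1,0.000000015919818,2020,polarity assumed
3,5.5.1,5.5,The proportion of beneficiaries participating in basic medical insurance,1,0.175002579995614,2020,polarity assumed
3,5.5.2,5.5,"The amount of funding per 10,000 people to participate in basic medical insurance",1,0.000000135310661,2020,polarity assumed
3,5.5.3,5.5,The proportion of outpatient and inpatient medical assistance recipients to the total population,1,0.044709025952675,2020,polarity assumed
3,5.5.4,5.5,"Outpatient and inpatient medical assistance funds per 10,000 people",1,0.310358147671988,2020,polarity assumed
3,6.1.1,6.1,"Total expenditure of medical and health institutions per 10,000 people",1,0.268397528567811,2021,polarity assumed
3,6.2.1,6.2,Total sales of drugs,1,0.457097995845349,2021,polarity assumed
3,6.2.2,6.2,Total sales of medical equipment,1,0.444561956797429,2021,polarity assumed
3,6.3.1,6.3,"Number of nursing beds per 10,000 people",1,0.268397519350026,2021,polarity assumed
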