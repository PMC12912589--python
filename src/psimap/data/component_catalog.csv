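model_no,country,component_name,direction,geocovariates
1,Botswana,Better material of roof,HSLS,NLIGHTS;LST;SLOPE;EVI;ACCESS
2,Botswana,Employed household members,HSLS,LST;SLOPE;DMROADSINT;POPPP
3,Botswana,Visited health facility for antenatal care,HSLS,DMROADSINT;POPPP
4,Botswana,Sick for at least 3 months in the past year,HSHS,LST;NDVI
5,Botswana,Household owns a working car,HSLS,LST
6,Eswatini,Better materials for exterior walls,HSLS,ACCESS;POPPP;DMROADS;DMROADSINT
7,Eswatini,Household size,HSHS,LST;ELEV;POPPP;ACCESS;DMROADSINT;EVI;SLOPE
8,Eswatini,Currently married or living with a partner,HSLS,LST;POPPP;ACCESS
9,Eswatini,Visited health facility for antenatal care,HSLS,LST;ELEV;ACCESS;POPPP;DMROADSINT
10,Eswatini,Household owns a working car,HSLS,ACCESS;ELEV
11,Lesotho,Household size,HSHS,ACCESS;LST;ELEV;DMROADS;NDVI
12,Lesotho,Sick for at least 3 months in the past year,HSHS,POPPP;NLIGHTS
13,Lesotho,Proportion of women,HSHS,SLOPE
14,Lesotho,Household owns a working car,HSLS,ACCESS;NLIGHTS;DMROADS
15,Malawi,Employed household members,HSLS,LST;NLIGHTS
16,Malawi,Household size,HSHS,ACCESS;DMROADS;ELEV;LST;EVI
17,Malawi,Household received economic support,HSHS,SLOPE
18,Malawi,Women currently pregnant,HSHS,LST;ELEV;DMWATER;NDVI
19,Malawi,Proportion of women,HSHS,ACCESS;DMROADS;POPPP;EVI
20,Malawi,Household owns a working mobile phone,HSLS,NLIGHTS;DMROADSINT;EVI;ACCESS
21,Mozambique,Better toilet facility type,HSLS,NLIGHTS;LST;DMWATER;DMROADS
22,Mozambique,Employed,HSLS,LST;DMWATER
23,Mozambique,Household size,HSHS,SLOPE
24,Mozambique,Visited health facility for antenatal care,HSLS,LST;NLIGHTS;ACCESS;ELEV
25,Mozambique,Proportion of women,HSHS,ACCESS;DMROADSINT
26,Mozambique,Household owns a working car,HSLS,DMWATER;DMROADSINT;DMROADS;NLIGHTS;LST
27,Nigeria,Material of household roof,HSLS,DMROADSINT;ACCESS;LST
28,Nigeria,Children per household,HSHS,LST;ELEV;NLIGHTS;ACCESS
29,Nigeria,Proportion of women,HSHS,LST;DMROADSINT;POPPP;ACCESS
30,Nigeria,Household owns a working refrigerator,HSLS,DMROADSINT;ELEV;LST;DMROADS;POPPP
31,Nigeria,Household owns a working motorcycle/scooter,HSLS,LST;ACCESS;DMROADS
32,Tanzania,Better floor material,HSLS,NLIGHTS;DMROADS;DMWATER;DMROADSINT;POPPP
33,Tanzania,Employed,HSLS,DMROADS
34,Tanzania,Number of rooms for sleeping,HSLS,POPPP
35,Tanzania,Proportion of women,HSHS,NLIGHTS;NDVI
36,Tanzania,Household owns a working motorcycle/scooter,HSLS,DMROADSINT
37,Uganda,Better household water source,HSLS,NLIGHTS;DMROADS;POPPP;ACCESS;SLOPE;NDVI
38,Uganda,Employed household members,HSLS,LST;NLIGHTS;DMROADSINT;DMROADS;DMWATER
39,Uganda,Married,HSLS,ACCESS;ELEV;SLOPE;EVI;LST
40,Uganda,Visited health facility for antenatal care,HSLS,ELEV;SLOPE;EVI;LST;DMROADS
41,Zambia,Better floor material,HSLS,ACCESS
42,Zambia,Employed household members,HSLS,ACCESS;POPPP;DMWATER;EVI
43,Zambia,Proportion of women,HSHS,NLIGHTS;DMROADSINT
44,Zambia,Household owns a working mobile phone,HSLS,ACCESS;SLOPE;NLIGHTS;POPPP
45,Zambia,Household owns a working motorcycle/scooter,HSLS,NLIGHTS;NDVI
46,Zimbabwe,Better toilet facility type,HSLS,EVI
47,Zimbabwe,Household size,HSHS,DMROADS;SLOPE
48,Zimbabwe,Married,HSLS,ACCESS;DMROADS
49,Zimbabwe,Women currently pregnant,HSHS,SLOPE
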