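index,label,domain_tag,origin
1,Mother too busy,caregiver,original_option
2,Vaccination site too far,access,original_option
3,Vaccine stockout,supply,original_option
4,Child was sick,caregiver,original_option
5,Fear of side effects,demand,original_option
6,Lack of information about vaccination,demand,original_option
7,Did not know where to go,demand,original_option
8,Did not know vaccines were needed,demand,original_option
9,Health facility closed,supply,original_option
10,Health worker absent,supply,original_option
11,Long waiting time at facility,supply,original_option
12,Cost of transport,access,original_option
13,Informal fees demanded,supply,original_option
14,Father or family opposed,caregiver,original_option
15,Religious opposition,demand,original_option
16,Distrust of health services,demand,original_option
17,Mother recently delivered,caregiver,original_option
18,Vaccination day inconvenient,access,original_option
19,Lost vaccination card,caregiver,original_option
20,Bad reception by health workers,supply,original_option
21,Insecurity on the way to facility,access,original_option
22,No reason given,other,original_option
23,"Travel, move, displacement",access,added_category
24,Negligence,caregiver,added_category
25,Vaccine schedule in progress,other,added_category
26,Health worker strike,supply,added_category
27,"War, armed conflict, ethnic conflict",access,added_category
28,Working in the field / agricultural work,caregiver,added_category
29,Child too young,other,added_category
30,Fear of Covid-19 vaccine,demand,added_category
31,Covid-19 lockdown,access,added_category
32,Covid-19 (fear of catching or vague),demand,added_category
33,Rumors,demand,added_category
34,Mother sick,caregiver,added_category
35,Child died or moved away,other,added_category
36,Flood or impassable road,access,added_category
37,Market day conflict,caregiver,added_category
38,Vaccinator never came to village,supply,added_category
39,Child already fully vaccinated,other,added_category
40,Waiting for a campaign,demand,added_category
41,Family conflict or separation,caregiver,added_category
42,Don't know the reason,other,added_category
43,Vague response,other,added_category
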