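treatment_id,study_label,cell_line,inoculum,dose_ug_per_ml,regimen_text,control_phases,treated_phases
1,Kamat et al.,HeyA8,250000,147,0.5 mg/kg thrice weekly for 3.5 weeks,0.1->1.2@3.5w,0.1->0.288@3.5w
2,Williams et al.,MAT-LyLu (MLL),1000000,392,Two doses of 7 mg/kg on days 4 and 11,0.5->4.8@10d,0.5->4.4@10d
3,Liu et al.,Hep-2,5000000,420,Two doses of 7.5 mg/kg/week,0.15->0.45@14d,0.15->0.09@6d;0.09->0.17@8d
4,Li et al.,PC-3,1000000,420,Three doses of 5 mg/kg on 6 days,0.57->1.93@11d,0.54->1.28@11d
5,Banerjee et al.,C4-2b,1000000,560,5 mg/kg body weight given i.v. every 3rd day (total of four doses),0.1->0.99@31.5d,0.1->0.371@31.5d
6,Williams et al.,MAT-LyLu (MLL),1000000,649.6,11.6 mg/kg on days 4 and 11,0.5->4.8@10d,0.5->1.63@10d
7,Sweeney et al.,MDA-MB-231,1000000,840,5 mg/kg/week for 6 weeks,0.06->0.24@14d,0.232->0.42@17d
8,Ichite et al.,A549,1000000,840,"10 mg/kg on days 14, 18 and 22",0.05->0.26@14d,0.05->0.09@14d
9,Kamat et al.,SKOV3ip1,1000000,840,15 mg/kg/2 weeks for 4 weeks,0.1->0.75@3.5w,0.1->0.2@3.5w
10,Kamat et al.,HeyA8 MDR,1000000,840,15 mg/kg/2 weeks for 4 weeks,0.1->2.2@3.5w,0.1->2.0@3.5w
11,Kamat et al.,HeyA8,250000,840,15 mg/kg/2 weeks for 4 weeks,0.1->1.2@3.5w,0.1->0.42@3.5w
12,Yoo et al.,HNSCC HN30,15000000,2100,7.5 mg/kg per injection twice a week for 6 weeks,0.4->1.7@35d,0.4->0.192@35d
13,Yoo et al.,HNSCC HN30,15000000,5040,15 mg/kg per injection twice a week for 6 weeks,0.4->1.7@35d,0.4->0.02@85d
14,Yoo et al.,HNSCC HN12,15000000,5040,15 mg/kg per injection twice a week for 6 weeks,0.25->2.5@35d,0.25->0.05@40d
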