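grouping,group,n_tasks,n_errors,rate
pathologist,P1,84,5,0.06
pathologist,P2,78,4,0.05
pathologist,P3,82,7,0.09
pathologist,P4,67,1,0.01
pathologist,P5,82,7,0.09
pathologist,P6,82,6,0.07
pathologist,P7,83,2,0.02
pathologist,P8,84,3,0.04
pathologist,P9,82,5,0.06
pathologist,P10,83,3,0.04
pathologist,P11,82,9,0.11
pathologist,P12,83,3,0.04
pathologist,P13,81,26,0.32
pathologist,P14,64,9,0.14
pathologist,P15,84,12,0.14
pathologist,P16,79,9,0.11
pathologist,P17,65,6,0.09
level,resident,310,47,0.15
level,junior,460,30,0.07
level,expert,411,27,0.07
level,senior,164,13,0.08
category,Neoplasia?,392,42,0.11
category,Malignant/benign?,258,11,0.04
category,Histopathological diagnosis?,388,35,0.09
category,Histotype?,160,2,0.01
category,Grade?,147,27,0.18
specimen,surgery,716,40,0.06
specimen,biopsy,629,77,0.12
subspecialty,breast,550,64,0.12
subspecialty,gastrointestinal,497,40,0.08
subspecialty,urology,298,13,0.04
total,total,1345,117,0.09
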