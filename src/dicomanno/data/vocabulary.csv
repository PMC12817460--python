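snomed_code,name,semantic_type,cui,ukhs_abbrev
818983003,Abdomen,Body Location or Region,C0000726,ABDOMEN
120574008,Upper extremity part,"Body Part, Organ, or Organ Component",C1268196,UP_EXM
85562004,Hand structure,"Body Part, Organ, or Organ Component",C0018563,HAND
127949000,Elbow,Body Location or Region,C0013769,ELBOW
8205005,Wrist,Body Location or Region,C0043262,WRIST
7569003,Finger,"Body Part, Organ, or Organ Component",C0016129,FINGER
76505004,Thumb structure,"Body Part, Organ, or Organ Component",C0040067,DAUMEN
85856004,Acromioclavicular joint structure,Body Space or Junction,C0001208,AC_GELENK
16982005,Shoulder,Body Location or Region,C0037004,SHOULDER
14975008,Forearm,"Body Part, Organ, or Organ Component",C0016536,UNTERARM
12921003,Pelvis,"Body Part, Organ, or Organ Component",C0030797,PELVIS
302524008,Entire distal femur,"Body Part, Organ, or Organ Component",C0448194,UP_LEG
72696002,Knee region structure,"Body Part, Organ, or Organ Component",C1963703,KNEE
56459004,Foot,"Body Part, Organ, or Organ Component",C0016504,FOOT
29836001,Hip structure,"Body Part, Organ, or Organ Component",C0019552,HIP
29707007,Toe,"Body Part, Organ, or Organ Component",C0040357,ZEHEN
344001,Ankle,Body Location or Region,C0003086,ANKLE
64234005,Bone structure of patella,Tissue,C0834406,PATELLA
120575009,Lower extremity part,"Body Part, Organ, or Organ Component",C1268197,LOW_EXM
76752008,Breast,"Body Part, Organ, or Organ Component",C0006141,BREAST
89546000,Bone structure of cranium,"Body Part, Organ, or Organ Component",C0037303,HEAD/SKULL
45206002,Nose,"Body Part, Organ, or Organ Component",C0028429,NASE
91609006,Mandible,"Body Part, Organ, or Organ Component",C0024687,JAW
51185008,Chest,Body Location or Region,C0817096,CHEST
113197003,Bone structure of rib,"Body Part, Organ, or Organ Component",C0035561,RIB
122494005,Cervical spine,"Body Part, Organ, or Organ Component",C0728985,CSPINE
122496007,Lumbar spine structure,Body Location or Region,C3887615,LSPINE
264232007,Thoracolumbar,Spatial Concept,C1443270,TLSPINE
122495006,Thoracic spine structure,"Body Part, Organ, or Organ Component",C0581269,TSPINE
51282000,Bone structure of spine,"Body Part, Organ, or Organ Component",C0549207,SSPINE
51299004,Bone structure of clavicle,"Body Part, Organ, or Organ Component",C0008913,CLAVICLE
54735007,Sacrum,"Body Part, Organ, or Organ Component",C0036037,KREUZBEIN
56873002,Sternum,"Body Part, Organ, or Organ Component",C0038293,STERNUM
-1,unknown,,,UNKNOWN
-2,report,,,REPORT
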