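leaf_code,level1,level2,level3
89546000,Cranium,Cranium,Cranium
45206002,Cranium,Cranium,Nose
91609006,Cranium,Cranium,Mandible
818983003,Abdomen,Abdomen,Abdomen
76752008,Chest,Breast,Breast
51185008,Chest,Chest,Chest
51299004,Chest,Clavicle,Clavicle
113197003,Chest,Rib,Rib
56873002,Chest,Sternum,Sternum
51282000,Spine,Spine,Spine
122494005,Spine,Cervical spine,Cervical spine
122495006,Spine,Thoracic spine,Thoracic spine
122496007,Spine,Lumbar spine,Lumbar spine
264232007,Spine,Thoracolumbar,Thoracolumbar
-1,Unknown,Unknown,Unknown
-2,Unknown,Report,Report
120574008,Upper extremity,Upper extremity,Upper extremity
16982005,Upper extremity,Shoulder,Shoulder
85856004,Upper extremity,Shoulder,Acromioclavicular joint
127949000,Upper extremity,Elbow,Elbow
14975008,Upper extremity,Forearm,Forearm
85562004,Upper extremity,Hand,Hand
8205005,Upper extremity,Hand,Wrist
7569003,Upper extremity,Hand,Finger
76505004,Upper extremity,Hand,Thumb
120575009,Lower Extremity,Lower Extremity,Lower Extremity
12921003,Lower Extremity,Pelvis,Pelvis
54735007,Lower Extremity,Pelvis,Sacrum
29836001,Lower Extremity,Pelvis,Hip
302524008,Lower Extremity,Distal femur,Distal femur
72696002,Lower Extremity,Knee,Knee
64234005,Lower Extremity,Knee,Patella
344001,Lower Extremity,Ankle,Ankle
56459004,Lower Extremity,Foot,Foot
29707007,Lower Extremity,Foot,Toe
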