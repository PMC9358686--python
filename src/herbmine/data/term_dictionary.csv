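raw,canonical,class,region,is_pain
Pain in interphalangeal joints,Upper limb joint pain,symptom,,
Wrist pain,Upper limb joint pain,symptom,,
Elbow pain,Upper limb joint pain,symptom,,
Shoulder pain,Upper limb joint pain,symptom,,
Ankle pain,Joint pain of lower extremity,symptom,,
Knee joint pain,Joint pain of lower extremity,symptom,,
Lower extremity joint pain,Joint pain of lower extremity,symptom,,
Lumbar pain,Lumbosacral pain,symptom,,
Hip pain,Lumbosacral pain,symptom,,
Sacral joint pain,Lumbosacral pain,symptom,,
Pain improvement,Pain reduction,symptom,,
Pain relief,Pain reduction,symptom,,
Difficulty bending,Unfavorable activity,symptom,,
Limb soreness,Limb discomfort,symptom,,
Neck discomfort,Limb discomfort,symptom,,
Burnout,Fatigue,symptom,,
Upper limb joint pain,Upper limb joint pain,symptom,upper_limb,1
Joint pain of lower extremity,Joint pain of lower extremity,symptom,lower_limb,1
Lumbosacral pain,Lumbosacral pain,symptom,lumbosacral,1
Polyarthralgia,Polyarthralgia,symptom,,1
Han Fangji,Fangji,herb,,
Panax notoginseng powder,Sanqi,herb,,
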