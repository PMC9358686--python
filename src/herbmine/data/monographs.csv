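name,count,property,flavors,meridians,category
Jinyinhua,182,Cold,Sweet,Stomach;Lung,Heat-clearing medicinal
Yiyiren,147,Cool,Sweet;Tasteless,Lung;Spleen;Stomach,Dampness-draining diuretic medicinal
Wugong,132,Warm,Pungent,Liver,Liver and wind-soothing medicine
Qingfengteng,115,Neutral,Pungent;Bitter,Liver;Spleen,Wind-dampness dispelling medicinal
Chaobaishao,107,Slightly cold,Bitter;Sour,Liver;Spleen,Tonifying and replenishing medicinal
Tusizi,94,Neutral,Pungent;Sweet,Liver;Spleen;Kidney,Tonifying and replenishing medicinal
Baizhu,91,Warm,Bitter;Sweet,Spleen;Stomach,Tonifying and replenishing medicinal
Fuzi,64,Extremely hot,Pungent;Sweet,Heart;Spleen;Kidney,Interior-warming medicinal
Guizhi,63,Warm,Pungent;Sweet,Lung;Bladder;Heart,Exterior-releasing medicinal
Qianghuo,62,Warm,Pungent;Bitter,Bladder;Kidney,Exterior-releasing medicinal
Tufuling,60,Neutral,Sweet;Tasteless,Liver;Kidney,Heat-clearing medicinal
Fangji,59,Cold,Bitter,Bladder;Lung,Wind-dampness dispelling medicinal
Sangjisheng,58,Neutral,Bitter;Sweet,Liver;Kidney,Wind-dampness dispelling medicinal
Shuizhi,56,Neutral,Salty;Bitter,Liver,Blood-activating and stasis-dispelling medicinal
Huainiuxi,55,Neutral,Bitter;Sour;Sweet,Liver;Kidney,Blood-activating and stasis-dispelling medicinal
Duhuo,54,Mild,Bitter;Tasteless,Bladder;Kidney,Wind-dampness dispelling medicinal
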