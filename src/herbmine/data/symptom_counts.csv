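symptom,count
Thready pulse,116
Joint pain of lower extremity,103
Upper limb joint pain,101
Poor sleep,98
Thin moss,84
White moss,78
Red tongue,69
Polyarthralgia,67
Inflexibility in body movements,66
Lumbosacral pain,64
Taut pulse,63
Fatigue,62
Loose stools,52
Morning stiffness,47
Physical discomfort,45
Dry mouth,45
Deep pulse,41
Dry eyes,38
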