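symptom	information_gain
Greasy fur	0.041751
Thready pulse	0.032381
Sublingual vein bruising	0.030248
Deep pulse	0.029555
Slippery pulse	0.023376
Taut pulse	0.022498
Drowsiness	0.020716
Red tongue	0.02046
Dark purple lips	0.015375
Excessive salivation	0.014193
Dim complexion	0.013139
Heat in the palms and soles	0.013014
Headache	0.013014
Dizziness	0.010641
Fatigue	0.009921
Dry stool and oliguria	0.009029
Emotional lability	0.008032
Timid low voice	0.006736
Constipation	0.005297
Numbness	0.004979
Thick fur	0.004949
High-pitched, coarse voice	0.004901
Limb limp	0.004516
Vomiting	0.004181
Night sweat	0.003487
Red face and eyes	0.003487
Limbs twitching	0.00335
Hand, foot swelling	0.00335
Pale tongue	0.00335
Plump tongue	0.00333
Purplish tongue	0.003244
Shortness of breath	0.003108
Thin fur	0.002897
Dull expression	0.002566
Yellow fur	0.002244
Spasm of nape	0.001819
Aching and weakness	0.001818
Sweat when quite	0.001461
Wry tongue	0.001401
Poor appetite	0.00134
Dark tongue	0.001255
Fatigue and drowsiness	0.001208
Pale red tongue	0.001147
Restless	0.000649
Sticky phlegm	0.000649
Uneven pulse	0.000649
Overweight	0.000615
Vexation and irritability	0.000577
Fever	0.000412
Palpitate	0.000369
Pale complexion	0.000137
Dry stool and constipation	4.85E-05
Apathy	3.93E-05
White fur	1.83E-05
Bitter taste in the mouth	1.72E-05
Reddish yellow urine	1.17E-05
Tinnitus	1.06E-05
Pale tongue	1.06E-05
Sweat after little movement	5.33E-06
Dark purple lips and dim complexion	5.33E-06
Ecchymosis on tongue	4.92E-06
Predilection for cold drink	1.96E-07
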