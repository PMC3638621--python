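core_symptom	term_id	term_name
Greasy fur	HP:0010298	Smooth tongue
Thready pulse
Sublingual vein bruising	HP:0000190	Abnormality of oral frenula
Sublingual vein bruising	HP:0000199	Tongue nodules
Sublingual vein bruising	HP:0000206	Glossitis
Sublingual vein bruising	HP:0000227	Tongue telangiectasia
Deep pulse
Slippery pulse
Taut pulse
Drowsiness	HP:0001262	Somnolence
Drowsiness	HP:0002329	Drowsiness
Drowsiness	HP:0002330	Paroxysmal drowsiness
Red tongue	HP:0000227	Tongue telangiectasia
Dark purple lips	HP:0000179	Thick lower lip vermilion
Dark purple lips	HP:0000205	Pursed lips
Dark purple lips	HP:0000214	Lip telangiectasia
Dark purple lips	HP:0000215	Thick upper lip vermilion
Dark purple lips	HP:0010798	Lip freckle
Excessive salivation	HP:0000197	Abnormality of parotid gland
Excessive salivation	HP:0002307	Drooling
Excessive salivation	HP:0003781	Excessive salivation
Excessive salivation	HP:0010286	Abnormality of the salivary glands
Excessive salivation	HP:0100755	Abnormality of salivation
Dim complexion	HP:0000980	Pallor
Dim complexion	HP:0008769	Dull facial expression
Heat in the palms and soles	HP:0007410	Palmoplantar hyperhidrosis
Headache	HP:0002076	Migraine
Headache	HP:0002315	Headache
Dizziness	HP:0002321	Vertigo
Fatigue	HP:0001279	Syncope
Fatigue	HP:0001324	Muscle weakness
Fatigue	HP:0003324	Generalized muscle weakness
Fatigue	HP:0003473	Fatigable weakness
Dry stool and oliguria	HP:0002019	Constipation
Dry stool and oliguria	HP:0100520	Oliguria
Emotional lability	HP:0000712	Emotional lability
Emotional lability	HP:0000720	Mood swings
Timid low voice	HP:0010300	Abnormally low-pitched voice
Timid low voice	HP:0001612	Weak cry
Constipation	HP:0002019	Constipation
Numbness	HP:0002495	Impaired vibratory sensation
Numbness	HP:0004372	Reduced consciousness/confusion
Thick fur
High-pitched, coarse voice	HP:0008377	High-pitched, coarse voice
Limb limp	HP:0002460	Distal muscle weakness
Limb limp	HP:0003690	Limb muscle weakness
Limb limp	HP:0003701	Proximal muscle weakness
Limb limp	HP:0007340	Lower limb muscle weakness
Vomiting	HP:0002013	Vomiting
Vomiting	HP:0002017	Nausea and vomiting
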