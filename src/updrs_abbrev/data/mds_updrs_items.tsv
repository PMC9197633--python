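# MDS-UPDRS instrument definition: 50 items, 65 rating fields (0-4 each).
# Columns: item_id, name, part, rating_fields (comma-separated), exclusion_reason.
# exclusion_reason: none | face_to_face | lower_limb
item_id	name	part	rating_fields	exclusion_reason
1.1	Cognitive impairment	1	1.1	none
1.2	Hallucinations and psychosis	1	1.2	none
1.3	Depressed mood	1	1.3	none
1.4	Anxious mood	1	1.4	none
1.5	Apathy	1	1.5	none
1.6	Features of dopamine dysregulation syndrome	1	1.6	none
1.7	Sleep problems	1	1.7	none
1.8	Daytime sleepiness	1	1.8	none
1.9	Pain and other sensations	1	1.9	none
1.10	Urinary problems	1	1.10	none
1.11	Constipation problems	1	1.11	none
1.12	Light headedness on standing	1	1.12	none
1.13	Fatigue	1	1.13	none
2.1	Speech	2	2.1	none
2.2	Saliva and drooling	2	2.2	none
2.3	Chewing and swallowing	2	2.3	none
2.4	Eating tasks	2	2.4	none
2.5	Dressing	2	2.5	none
2.6	Hygiene	2	2.6	none
2.7	Handwriting	2	2.7	none
2.8	Doing hobbies and other activities	2	2.8	none
2.9	Turning in bed	2	2.9	none
2.10	Tremor	2	2.10	none
2.11	Getting out of bed, a car, or a deep chair	2	2.11	none
2.12	Walking and balance	2	2.12	none
2.13	Freezing	2	2.13	none
3.1	Speech	3	3.1	none
3.2	Facial expression	3	3.2	none
3.3	Rigidity	3	3.3.neck,3.3.RUE,3.3.LUE,3.3.RLE,3.3.LLE	face_to_face
3.4	Finger tapping	3	3.4.R,3.4.L	none
3.5	Hand movements	3	3.5.R,3.5.L	none
3.6	Pronation-supination movements of hands	3	3.6.R,3.6.L	none
3.7	Toe tapping	3	3.7.R,3.7.L	lower_limb
3.8	Leg agility	3	3.8.R,3.8.L	lower_limb
3.9	Arising from chair	3	3.9	none
3.10	Gait	3	3.10	lower_limb
3.11	Freezing of gait	3	3.11	lower_limb
3.12	Postural stability	3	3.12	face_to_face
3.13	Posture	3	3.13	lower_limb
3.14	Global spontaneity of movement (body bradykinesia)	3	3.14	lower_limb
3.15	Postural tremor of the hands	3	3.15.R,3.15.L	none
3.16	Kinetic tremor of the hands	3	3.16.R,3.16.L	none
3.17	Rest tremor amplitude	3	3.17.RUE,3.17.LUE,3.17.RLE,3.17.LLE,3.17.lipjaw	none
3.18	Constancy of rest tremor	3	3.18	none
4.1	Time spent with dyskinesias	4	4.1	none
4.2	Functional impact of dyskinesias	4	4.2	none
4.3	Time spent in the off state	4	4.3	none
4.4	Functional impact of fluctuations	4	4.4	none
4.5	Complexity of motor fluctuations	4	4.5	none
4.6	Painful off-state dystonia	4	4.6	none
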