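#version	stub-24.1-subset
Depression	psychiatric
Depressive disorder	psychiatric
Major depression	psychiatric
Depressed mood	psychiatric
Anxiety	psychiatric
Anxiety disorder	psychiatric
Mixed anxiety and depressive disorder	psychiatric
Social anxiety disorder	psychiatric
Panic attack	psychiatric
Bipolar disorder	psychiatric
Bipolar I disorder	psychiatric
Mania	psychiatric
Hypomania	psychiatric
Schizoaffective disorder	psychiatric
Schizophreniform disorder	psychiatric
Psychotic disorder	psychiatric
Acute psychosis	psychiatric
Delusional disorder, persecutory type	psychiatric
Paranoia	psychiatric
Delirium	psychiatric
Confusional state	psychiatric
Disorientation	psychiatric
Hallucination	psychiatric
Hallucination, visual	psychiatric
Hallucination, auditory	psychiatric
Sleep disorder	psychiatric
Sleep disorder - insomnia type	psychiatric
Insomnia	psychiatric
Initial insomnia	psychiatric
Middle insomnia	psychiatric
Terminal insomnia	psychiatric
Poor quality sleep	psychiatric
Abnormal dreams	psychiatric
Nightmare	psychiatric
Sleep terror	psychiatric
Somnambulism	psychiatric
Rapid eye movement sleep behaviour disorder	psychiatric
Suicidal ideation	psychiatric
Suicidal behaviour	psychiatric
Suicide attempt	psychiatric
Suspected suicide	psychiatric
Completed suicide	psychiatric
Intentional self-injury	psychiatric
Self-injurious ideation	psychiatric
Feelings of worthlessness	psychiatric
Agitation	psychiatric
Restlessness	psychiatric
Irritability	psychiatric
Aggression	psychiatric
Anger	psychiatric
Mood swings	psychiatric
Affect lability	psychiatric
Euphoric mood	psychiatric
Dysphoria	psychiatric
Tearfulness	psychiatric
Apathy	psychiatric
Emotional distress	psychiatric
Emotional disorder	psychiatric
Nervousness	psychiatric
Fear	psychiatric
Stress	psychiatric
Libido decreased	psychiatric
Eating disorder	psychiatric
Adjustment disorder	psychiatric
Post-traumatic stress disorder	psychiatric
Obsessive-compulsive disorder	psychiatric
Mental disorder	psychiatric
Mental status changes	psychiatric
Bruxism	psychiatric
Nausea	other
Vomiting	other
Diarrhoea	other
Constipation	other
Abdominal pain	other
Abdominal distension	other
Dyspepsia	other
Flatulence	other
Gastritis	other
Gastrooesophageal reflux disease	other
Dry mouth	other
Headache	other
Dizziness	other
Paraesthesia	other
Fatigue	other
Asthenia	other
Malaise	other
Pyrexia	other
Rash	other
Urticaria	other
Pruritus	other
Alopecia	other
Arthralgia	other
Myalgia	other
Bone fracture	other
Osteoporosis	other
Dyspnoea	other
Cough	other
Chest pain	other
Palpitations	other
Hypertension	other
Oedema peripheral	other
Renal impairment	other
Hepatic enzyme increased	other
Anaemia	other
Vitamin B12 deficiency	other
Hypomagnesaemia	other
Weight decreased	other
Weight increased	other
Drug ineffective	other
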