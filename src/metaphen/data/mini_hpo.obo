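format-version: 1.2
data-version: metaphen/mini/2024
remark: Synthetic mini phenotype ontology for metaphen tests and examples. Term identifiers follow the HP CURIE convention but this file is a hand-built subset, not an HPO release.
ontology: mini-hp

[Term]
id: HP:0000001
name: All

[Term]
id: HP:0000118
name: Phenotypic abnormality
is_a: HP:0000001

[Term]
id: HP:0100022
name: Abnormality of movement
is_a: HP:0000118

[Term]
id: HP:0012332
name: Abnormal autonomic nervous system physiology
is_a: HP:0000118

[Term]
id: HP:0002360
name: Sleep abnormality
is_a: HP:0000118

[Term]
id: HP:0011446
name: Abnormality of higher mental function
is_a: HP:0000118

[Term]
id: HP:0002795
name: Abnormal respiratory system physiology
is_a: HP:0000118

[Term]
id: HP:0004408
name: Abnormality of the sense of smell
is_a: HP:0000118

[Term]
id: HP:0003474
name: Somatic sensory dysfunction
is_a: HP:0000118

[Term]
id: HP:0001337
name: Tremor
is_a: HP:0100022

[Term]
id: HP:0002322
name: Resting tremor
is_a: HP:0001337

[Term]
id: HP:0031908
name: Pill-rolling tremor
is_a: HP:0002322

[Term]
id: HP:0002174
name: Postural tremor
is_a: HP:0001337

[Term]
id: HP:0002345
name: Action tremor
is_a: HP:0001337

[Term]
id: HP:0001300
name: Parkinsonism
is_a: HP:0100022

[Term]
id: HP:0002067
name: Bradykinesia
is_a: HP:0001300

[Term]
id: HP:0002063
name: Rigidity
is_a: HP:0100022

[Term]
id: HP:0001288
name: Gait disturbance
is_a: HP:0100022

[Term]
id: HP:0002066
name: Gait ataxia
is_a: HP:0001288

[Term]
id: HP:0002317
name: Unsteady gait
is_a: HP:0001288

[Term]
id: HP:0002172
name: Postural instability
is_a: HP:0100022

[Term]
id: HP:0002527
name: Falls
is_a: HP:0002172

[Term]
id: HP:0000605
name: Supranuclear gaze palsy
is_a: HP:0100022

[Term]
id: HP:0001260
name: Dysarthria
is_a: HP:0100022

[Term]
id: HP:0002015
name: Dysphagia
is_a: HP:0100022

[Term]
id: HP:0030015
name: Alien limb phenomenon
is_a: HP:0100022

[Term]
id: HP:0001278
name: Orthostatic hypotension
is_a: HP:0012332

[Term]
id: HP:0000802
name: Erectile dysfunction
is_a: HP:0012332

[Term]
id: HP:0000020
name: Urinary incontinence
is_a: HP:0012332

[Term]
id: HP:0002019
name: Constipation
is_a: HP:0012332

[Term]
id: HP:0033696
name: REM sleep behavior disorder
is_a: HP:0002360

[Term]
id: HP:0100785
name: Insomnia
is_a: HP:0002360

[Term]
id: HP:0001262
name: Excessive daytime somnolence
is_a: HP:0002360

[Term]
id: HP:0100543
name: Cognitive impairment
is_a: HP:0011446

[Term]
id: HP:0033725
name: Mild cognitive impairment
is_a: HP:0100543

[Term]
id: HP:0000726
name: Dementia
is_a: HP:0100543

[Term]
id: HP:0002354
name: Memory impairment
is_a: HP:0100543

[Term]
id: HP:0000738
name: Hallucinations
is_a: HP:0011446

[Term]
id: HP:0010307
name: Stridor
is_a: HP:0002795

[Term]
id: HP:0000458
name: Anosmia
is_a: HP:0004408

[Term]
id: HP:0032147
name: Cortical sensory loss
is_a: HP:0003474

[Term]
id: HP:0007777
name: obsolete Parkinsonian tremor
is_obsolete: true
replaced_by: HP:0002322
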