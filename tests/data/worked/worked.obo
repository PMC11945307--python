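format-version: 1.2
remark: hand-written 12-node worked fixture (diamond + chain), 20 genes

[Term]
id: T:01
name: disease

[Term]
id: T:02
name: disease of anatomical entity
is_a: T:01 ! disease

[Term]
id: T:03
name: disease of cellular proliferation
is_a: T:01 ! disease

[Term]
id: T:04
name: neurodegenerative disease
is_a: T:02 ! disease of anatomical entity
is_a: T:03 ! disease of cellular proliferation

[Term]
id: T:05
name: dementia
is_a: T:04 ! neurodegenerative disease

[Term]
id: T:06
name: tauopathy
is_a: T:05 ! dementia

[Term]
id: T:07
name: alzheimer's disease
synonym: "AD" EXACT []
synonym: "alzheimer dementia" EXACT []
is_a: T:06 ! tauopathy

[Term]
id: T:08
name: organ system cancer
is_a: T:02 ! disease of anatomical entity

[Term]
id: T:09
name: carcinoma
is_a: T:08 ! organ system cancer

[Term]
id: T:10
name: colorectal carcinoma
is_a: T:03 ! disease of cellular proliferation

[Term]
id: T:11
name: intestinal benign neoplasm
is_a: T:10 ! colorectal carcinoma
is_a: T:02 ! disease of anatomical entity

[Term]
id: T:12
name: rectum cancer
is_a: T:11 ! intestinal benign neoplasm
is_a: T:03 ! disease of cellular proliferation

[Term]
id: T:99
name: retired disease concept
is_a: T:01 ! disease
is_obsolete: true
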