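sample_id	sex	stage	replicate
BJ1	male	3-5h	1
BJ2	male	3-5h	2
BJ3	female	3-5h	1
BJ4	female	3-5h	2
BJ5	male	2-3h	1
BJ6	male	2-3h	2
BJ7	female	2-3h	1
BJ8	female	2-3h	2
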