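crista_id,length_um,n_segments,cjs_per_segment,cj_ends,cj_diameter_nm
C1,0.41,3,2.0,both,16
C2,0.50,2,2.5,both,18
C3,0.58,2,2.0,both,17
C4,0.71,2,2.3,both,15
C5,0.86,2,1.9,both,22
C6,0.79,3,2.33,both,14
C7,0.55,1,2.0,one,17
C8,0.60,1,3.0,one,19
C9,0.80,1,1.0,one,12
C10,1.18,4,2.25,both,18
C11,0.62,1,2.0,one,16
C12,1.35,4,2.5,both,21
C13,1.42,5,2.2,both,17
C14,1.46,3,2.33,both,15
C15,1.30,5,2.4,both,20
C16,0.63,1,1.5,one,13
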