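# SYNTHETIC reconstruction of a MAC/ACE titration from published summary
# parameters (MAC: n=0.62, cu_half=9.7e-20 M; ACE: n=0.90, cu_half=2.8e-18 M).
# Not digitized measurements. Ligand axis: hypothetical 'free' Cu, molar.
protein	ligand_concentration_M	apo_fraction
MAC	5.162909e-17	0.020000
MAC	6.209252e-18	0.070526
MAC	2.373904e-18	0.121053
MAC	1.229290e-18	0.171579
MAC	7.324449e-19	0.222105
MAC	4.722327e-19	0.272632
MAC	3.196177e-19	0.323158
MAC	2.231144e-19	0.373684
MAC	1.587725e-19	0.424211
MAC	1.141871e-19	0.474737
MAC	8.239988e-20	0.525263
MAC	5.926087e-20	0.575789
MAC	4.217119e-20	0.626316
MAC	2.943830e-20	0.676842
MAC	1.992450e-20	0.727368
MAC	1.284602e-20	0.777895
MAC	7.654014e-21	0.828421
MAC	3.963514e-21	0.878947
MAC	1.515319e-21	0.929474
MAC	1.822422e-22	0.980000
ACE	2.114237e-16	0.020000
ACE	4.914459e-17	0.070526
ACE	2.534032e-17	0.121053
ACE	1.610355e-17	0.171579
ACE	1.127210e-17	0.222105
ACE	8.330853e-18	0.272632
ACE	6.366568e-18	0.323158
ACE	4.970128e-18	0.373684
ACE	3.931722e-18	0.424211
ACE	3.133015e-18	0.474737
ACE	2.502382e-18	0.525263
ACE	1.994037e-18	0.575789
ACE	1.577424e-18	0.626316
ACE	1.231433e-18	0.676842
ACE	9.410801e-19	0.727368
ACE	6.955228e-19	0.777895
ACE	4.868493e-19	0.828421
ACE	3.093884e-19	0.878947
ACE	1.595293e-19	0.929474
ACE	3.708193e-20	0.980000
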