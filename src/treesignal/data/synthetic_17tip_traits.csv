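tip,BM,random,clade
t1,-0.8186822708887587,0.4564573131436212,-1.1651538947194855
t2,-1.2382765361909014,-0.041183859334056286,-0.3214325660953865
t3,0.081829913812345,1.5073322055297704,3.8878631178234064
t4,-0.7825335586050872,0.23846665630714745,4.571055450502911
t5,-1.598917969027463,-0.08837879277054132,3.0256331555985825
t6,-1.5489430588130149,-0.39945203109425453,3.162194287773502
t7,-1.1811242595716693,-0.7556770403073303,2.236329016398354
t8,0.11570730973861923,0.3732941507530342,0.22648586952944183
t9,0.30089212151154837,1.9605905743413057,-0.18056732719820826
t10,-1.3422650675591132,0.0974031357862833,0.2026180697245548
t11,-1.7023201014043245,-0.38666169253140537,0.08543473451538143
t12,-2.0817830930232315,-0.5058130988672378,-0.09788163182984151
t13,-0.42456249531550555,-0.9047694510492732,-0.49860651933627054
t14,-0.08600324574120272,-0.6497691810760743,-0.33058170304143436
t15,-0.04557506047283552,-0.9008309145477209,-0.8265906953544979
t16,1.2465704580477426,1.2079560472366535,-0.3937391973567179
t17,1.1050181001993473,0.10581480042374788,0.018060051832615616
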