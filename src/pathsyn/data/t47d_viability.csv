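arm,replicate_index,viability
bleomycin,1,0.8651
bleomycin,2,0.8308
bleomycin,3,1.1593
bleomycin,4,0.8374
bleomycin,5,0.8043
bleomycin,6,0.7598
bleomycin,7,0.6332
bleomycin,8,0.8417
bortezomib,1,0.7793
bortezomib,2,0.7798
bortezomib,3,0.8857
bortezomib,4,0.8288
bortezomib,5,0.8641
bortezomib,6,0.7557
bortezomib,7,0.5992
bortezomib,8,0.6336
combination_1,1,0.6603
combination_1,2,0.7207
combination_1,3,0.7435
combination_1,4,0.7579
combination_1,5,0.5590
combination_1,6,0.6598
combination_1,7,0.5037
combination_1,8,0.6431
combination_2,1,0.6315
combination_2,2,0.5755
combination_2,3,0.6951
combination_2,4,0.7582
combination_2,5,0.6176
combination_2,6,0.6719
combination_2,7,0.4989
combination_2,8,0.6852
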