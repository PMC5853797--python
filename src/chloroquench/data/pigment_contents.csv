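block,genotype,parental_wt,condition,chl_content,chl_content_sd,chl_a_b,chl_a_b_sd,chl_car,chl_car_sd
large,Col-0,Col-0,before,1190.9,113.6,2.9,0.2,4.2,0.1
large,Col-0,Col-0,after,954.5,27.3,3.7,0.2,3.7,0.1
large,arc6-5,Col-0,before,1002.4,62.94,3.07,0.16,4.23,0.01
large,arc6-5,Col-0,after,781,35.4,5.2,0.6,3.4,0.1
large,arc5-2,Col-0,before,979.7,11.9,3.2,0.3,4.2,0.1
large,arc5-2,Col-0,after,898.7,15.6,3.8,0.1,3.7,0.04
large,arc12,Col-0,before,1032.3,14.9,3.03,0.2,4.2,0.1
large,arc12,Col-0,after,841.8,26.3,4.2,0.4,3.6,0.1
large,pdv1-1,Col-0,before,1095.7,42.4,2.8,0.1,4.2,0.1
large,pdv1-1,Col-0,after,1002.9,46.2,4.5,0.7,3.7,0.02
large,pdv2-1,Col-0,before,1038.9,62.6,3.1,0.3,4.3,0.1
large,pdv2-1,Col-0,after,869.1,74,3.9,0.4,3.7,0.1
large,pdv1-1 pdv2-1,Col-0,before,1185.1,83.8,3.6,0.4,4.2,0.2
large,pdv1-1 pdv2-1,Col-0,after,878.6,35.8,4.0,0.5,3.7,0.1
intermediate,Col-0,Col-0,before,1107.2,41.7,2.6,0.1,4.2,0.1
intermediate,Col-0,Col-0,after,893.7,21.1,3.4,0.1,3.9,0.1
intermediate,ftsZ1-1,Col-0,before,1069.6,43.2,3.4,0.2,4.1,0.03
intermediate,ftsZ1-1,Col-0,after,793.6,46.2,3.8,0.2,3.7,0.1
intermediate,ftsZ2-2,Col-0,before,1024.5,76.9,3.3,0.3,4.1,0.05
intermediate,ftsZ2-2,Col-0,after,893.1,9.12,3.8,0.1,3.8,0.03
intermediate,arc3-2,Col-0,before,1049.03,23.3,2.9,0.3,4.3,0.1
intermediate,arc3-2,Col-0,after,744.8,38.33,4.0,0.2,3.6,0.03
intermediate,fzl,Col-0,before,984.1,62.9,3.2,0.3,3.9,0.1
intermediate,fzl,Col-0,after,788.5,36.16,4.3,0.1,3.5,0.1
intermediate,parc6-1,Col-0,before,1024.9,47.3,3.1,0.1,4.3,0.1
intermediate,parc6-1,Col-0,after,747.3,41.54,4.7,0.2,3.5,0.04
intermediate,Ler,Ler,before,1069.5,55.7,2.5,0.2,4.4,0.05
intermediate,Ler,Ler,after,945.9,29.2,4.1,0.4,3.7,0.1
intermediate,arc11,Ler,before,1009.2,80.4,2.9,0.1,4.5,0.1
intermediate,arc11,Ler,after,925.9,16.3,4.4,0.5,3.6,0.003
intermediate,Ws-2,Ws-2,before,1013,86.2,2.5,0.2,4.4,0.2
intermediate,Ws-2,Ws-2,after,795.9,47.9,4.02,0.4,3.7,0.1
intermediate,minD1-1,Ws-2,before,1092.4,69.5,2.8,0.3,4.4,0.1
intermediate,minD1-1,Ws-2,after,752.9,71.04,4.3,0.1,3.6,0.1
small,Col-0,Col-0,before,1070.5,64.2,2.8,0.04,4.1,0.02
small,Col-0,Col-0,after,847.3,39.5,3.3,0.2,3.6,0.1
small,35S-PDV1 35S-PDV2,Col-0,before,929.8,60.3,2.8,0.1,4.2,0.1
small,35S-PDV1 35S-PDV2,Col-0,after,832.5,29.7,3.3,0.2,3.5,0.1
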