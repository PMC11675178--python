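model,egg,measure,mask_mm,voxel_estimate_mm,physical_mm,output_estimate_mm
unet,1,thickness,1.6260,1.4634,0.3700,0.4479
unet,1,height,59.1855,59.8359,59.8800,64.5472
unet,1,width,45.5273,44.8770,45.4500,48.7350
unet,2,thickness,1.9512,1.7886,0.3200,0.3876
unet,2,height,57.2344,57.8848,59.5200,61.7045
unet,2,width,43.5762,43.5762,43.4400,46.7352
unet,3,thickness,1.3008,1.1382,0.3900,0.4246
unet,3,height,59.8359,59.1855,59.4200,63.9901
unet,3,width,45.5273,45.5273,43.2800,48.0945
unet,4,thickness,1.4634,1.6260,0.4000,0.4378
unet,4,height,58.5352,58.5352,59.3100,59.5307
unet,4,width,42.2754,43.5762,42.6000,44.5303
unet,5,thickness,1.6260,1.3008,0.3600,0.3516
unet,5,height,55.2832,56.5840,56.8700,61.4720
unet,5,width,44.2266,44.2266,43.9700,46.4149
unet,6,thickness,1.3008,1.4634,0.3700,0.4443
unet,6,height,61.7871,61.1367,61.8000,64.2553
unet,6,width,44.2266,44.8770,44.7700,48.4615
unet,7,thickness,1.3008,1.4634,0.3400,0.3696
unet,7,height,57.8848,56.5840,57.8200,62.4110
unet,7,width,44.2266,43.5762,43.6300,47.3255
unet,8,thickness,0.9756,1.3008,0.2900,0.4598
unet,8,height,57.2344,57.8848,57.5300,62.3857
unet,8,width,44.2266,44.8770,44.2800,47.2127
unet,9,thickness,1.1382,1.6260,0.3600,0.3945
unet,9,height,59.1855,58.5352,59.3300,63.9301
unet,9,width,46.1777,46.8281,46.5800,48.2832
unet,10,thickness,1.1382,1.6260,0.3300,0.2728
unet,10,height,56.5840,54.6328,55.7600,60.0560
unet,10,width,42.9258,42.9258,44.0800,45.7268
unet,11,thickness,1.4634,1.3008,0.3600,0.3209
unet,11,height,57.8848,56.5840,58.2000,61.6495
unet,11,width,43.5762,43.5762,43.5300,46.8414
fcn,1,thickness,1.6260,1.1382,0.3700,0.3949
fcn,1,height,59.1855,59.1855,59.8800,60.3605
fcn,1,width,42.9258,44.8770,45.4500,45.2794
fcn,2,thickness,1.9512,0.9756,0.3200,0.3583
fcn,2,height,57.2344,57.2344,59.5200,58.9571
fcn,2,width,43.5762,43.5762,43.4400,44.1526
fcn,3,thickness,1.3008,1.3008,0.3900,0.3054
fcn,3,height,59.8359,59.8359,59.4200,59.7758
fcn,3,width,45.5273,45.5273,45.5400,44.6681
fcn,4,thickness,1.4634,1.1382,0.4000,0.3133
fcn,4,height,58.5352,57.8847,59.3100,57.7527
fcn,4,width,42.2754,42.9258,42.6000,42.9015
fcn,5,thickness,1.6260,1.3008,0.3600,0.2110
fcn,5,height,55.2832,55.9336,56.8700,57.4620
fcn,5,width,44.2266,43.5762,43.9700,43.0780
fcn,6,thickness,1.3008,0.9756,0.3700,0.4490
fcn,6,height,61.7871,61.1367,61.8000,60.7595
fcn,6,width,44.2266,44.8770,44.7700,45.2866
fcn,7,thickness,1.3008,1.1382,0.3400,0.2664
fcn,7,height,57.8848,57.2344,57.8200,58.8440
fcn,7,width,44.2266,43.5762,43.6300,44.1922
fcn,8,thickness,0.9756,0.9756,0.2900,0.3108
fcn,8,height,57.2344,55.2832,57.5300,58.1743
fcn,8,width,44.2266,44.2266,44.2800,44.2006
fcn,9,thickness,1.1382,1.3008,0.3600,0.2259
fcn,9,height,59.1855,58.5351,59.3300,59.3228
fcn,9,width,46.1777,46.8281,46.5800,44.6234
fcn,10,thickness,1.1382,1.3008,0.3300,0.2882
fcn,10,height,56.5840,54.6328,55.7600,56.4656
fcn,10,width,42.9258,43.5762,44.0800,43.3312
fcn,11,thickness,1.4634,0.9756,0.3600,0.2100
fcn,11,height,57.8848,56.5840,58.2000,58.7781
fcn,11,width,43.5762,42.9258,43.5300,44.3173
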