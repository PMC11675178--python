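model,class_name,true_voxels,estimated_voxels,mean_precision,mean_recall
unet,shell,64293,69017,0.7872,0.8524
unet,yolk,141965,141874,0.8507,0.849
unet,albumen,244697,244951,0.8868,0.8885
unet,air_cell,14660,13695,0.8934,0.8327
fcn,shell,64293,63465,0.7071,0.7044
fcn,yolk,141965,141265,0.8468,0.8437
fcn,albumen,244697,248745,0.8508,0.8648
fcn,air_cell,14660,13595,0.7516,0.619
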