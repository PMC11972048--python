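fold,cph_clinical,mlp_clinical,resnet_volume,late_average,early_cph,early_mlp,joint_late,jeps
1,0.723,0.652,0.696,0.768,0.411,0.643,0.589,0.705
2,0.955,0.786,0.714,0.830,0.455,0.732,0.679,0.857
3,0.696,0.598,0.688,0.688,0.946,0.580,0.786,0.759
4,0.854,0.740,0.677,0.771,0.646,0.700,0.594,0.729
5,0.667,0.708,0.688,0.750,0.365,0.781,0.792,0.792
6,0.490,0.531,0.656,0.615,0.677,0.562,0.594,0.635
7,0.771,0.646,0.635,0.677,0.646,0.700,0.771,0.844
8,0.750,0.573,0.635,0.635,0.083,0.573,0.448,0.615
9,0.613,0.844,0.500,0.812,0.229,0.875,0.677,0.896
10,0.678,0.822,0.689,0.911,0.244,0.822,0.722,0.956
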