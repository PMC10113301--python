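plant,anther_height_cm,b0,b1,b2
Aechmea araneosa,1.76,5.086,0.749,-0.043
Aechmea lamarchei,2.50,4.927,0.943,-0.058
Aechmea mutica,3.06,6.227,0.320,-0.014
Aphelandra margaritae,4.73,5.906,0.157,-0.004
Billbergia amoena,5.51,3.684,0.852,-0.036
Nidularium cariacicaense,4.84,4.409,0.539,-0.021
Nidularium procerum,4.11,3.343,0.685,-0.025
Quesnelia quesneliana,3.24,6.466,0.342,-0.014
Quesnelia strobilispica,4.95,10.661,-0.549,0.021
Tillandsia stricta,0.67,4.362,0.383,-0.018
Vriesea ensiformis,5.56,6.183,0.246,-0.004
Vriesea simplex,7.67,8.235,-0.267,0.016
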