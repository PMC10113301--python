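pollinator,Aechmea araneosa,Aechmea lamarchei,Aechmea mutica,Aphelandra margaritae,Billbergia amoena,Nidularium cariacicaense,Nidularium procerum,Quesnelia quesneliana,Quesnelia strobilispica,Tillandsia stricta,Vriesea ensiformis,Vriesea simplex
Phaethornis eurynome,6,10,2,54,0,78,3,0,0,5,25,1
Phaethornis squalidus,7,0,0,0,0,0,0,0,0,0,0,0
Ramphodon naevius,69,23,28,0,4,18,24,10,16,0,0,4
Thalurania glaucopis,96,4,0,0,0,0,0,0,1,0,0,0
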