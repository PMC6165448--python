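name,low,high,role,assignment
3500_3200,3200,3500,core,O-H and N-H symmetric stretching of alcohols and amides/proteins
3100_3020,3020,3100,core,vinyl C-H stretching of unsaturated lipids
2950_2920,2920,2950,core,methyl/methylene asymmetric stretching of lipids
2852,2844,2860,core,methylene symmetric stretching of lipids
1744,1736,1752,core,C=O stretching of triglyceride ester carbonyl
1627,1619,1635,core,amide I C=O stretching (beta-sheet region)
1541,1533,1549,core,amide II N-H bending with C-N stretching of proteins
1450,1442,1458,core,C-H asymmetric stretching of protein moieties
1395,1387,1403,core,C-H symmetric stretching of protein moieties
1240,1232,1248,core,P=O asymmetric stretching of phospholipids/nucleic acids
1170_1154,1154,1170,core,C-O stretching of proteins and triglycerides
1117,1109,1125,core,C-H bending and deformation of fatty acids
1040_1020,1020,1040,core,carbohydrate moieties (glycogen indicator)
966,958,974,core,trans CH=CH out-of-plane deformation
870,862,878,core,para-disubstituted aromatic derivatives
717,709,725,aux,cis -CH=CH- out-of-plane bending of unsaturated fatty acids
1083,1075,1091,aux,P=O symmetric stretching of phospholipids/nucleic acids
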