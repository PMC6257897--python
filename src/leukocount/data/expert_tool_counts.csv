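individual,wbc_class,expert,tool
1,NEUTROPHIL,23,21
1,LYMPHOCYTE,13,14
1,BASOPHIL,2,2
1,MONOCYTE,1,1
1,EOSINOPHIL,2,3
2,NEUTROPHIL,16,14
2,LYMPHOCYTE,7,8
2,BASOPHIL,0,0
2,MONOCYTE,0,0
2,EOSINOPHIL,0,0
3,NEUTROPHIL,14,18
3,LYMPHOCYTE,13,14
3,BASOPHIL,0,0
3,MONOCYTE,0,0
3,EOSINOPHIL,1,1
4,NEUTROPHIL,17,13
4,LYMPHOCYTE,13,17
4,BASOPHIL,0,0
4,MONOCYTE,0,0
4,EOSINOPHIL,1,1
5,NEUTROPHIL,24,23
5,LYMPHOCYTE,16,17
5,BASOPHIL,1,1
5,MONOCYTE,1,1
5,EOSINOPHIL,0,0
6,NEUTROPHIL,15,14
6,LYMPHOCYTE,7,7
6,BASOPHIL,1,1
6,MONOCYTE,1,1
6,EOSINOPHIL,1,2
7,NEUTROPHIL,14,12
7,LYMPHOCYTE,10,12
7,BASOPHIL,0,0
7,MONOCYTE,0,0
7,EOSINOPHIL,0,0
8,NEUTROPHIL,23,20
8,LYMPHOCYTE,9,11
8,BASOPHIL,0,0
8,MONOCYTE,0,0
8,EOSINOPHIL,0,1
9,NEUTROPHIL,14,12
9,LYMPHOCYTE,7,8
9,BASOPHIL,1,1
9,MONOCYTE,2,2
9,EOSINOPHIL,0,1
10,NEUTROPHIL,24,21
10,LYMPHOCYTE,7,9
10,BASOPHIL,0,0
10,MONOCYTE,0,0
10,EOSINOPHIL,0,1
11,NEUTROPHIL,14,13
11,LYMPHOCYTE,5,7
11,BASOPHIL,0,0
11,MONOCYTE,4,3
11,EOSINOPHIL,0,0
12,NEUTROPHIL,19,17
12,LYMPHOCYTE,11,13
12,BASOPHIL,0,0
12,MONOCYTE,0,0
12,EOSINOPHIL,0,0
13,NEUTROPHIL,21,19
13,LYMPHOCYTE,6,7
13,BASOPHIL,0,0
13,MONOCYTE,1,1
13,EOSINOPHIL,1,2
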