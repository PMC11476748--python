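sample	species	profile
1-P. altebilobata	P. altebilobata	BICCACBBFL00CCDD
2-P. edulis	P. edulis	IIDDJLCFLL00CCDD
3-P. edulis	P. edulis	II00JJCCLLCCCCDD
4-P. edulis	P. edulis	BIDDJJCCLLACCCDD
5-P. edulis	P. edulis	IIDDJJCCLLCCCCDD
6-P. edulis	P. edulis	IIDDJLCCLLCCCCDD
7-P. edulis "gui han yi hao" (seeding)	P. edulis	GIDFJL00LLCDCEFF
8-P. edulis "gui han yi hao" (seeding)	P. edulis	IIFFJJFFLLCDEEFF
9-P. edulis "gui han yi hao" (seeding)	P. edulis	GIDDJJFFLLCDCCFF
10-P. edulis "hei mei ren"	P. edulis	GIFFJJFFLLDDEEFF
11-P. edulis "man tian xing"	P. edulis	IIDDJJFFLLAACCDD
12-P. edulis "man tian xing"	P. edulis	IIDDJJFFLLAACCDD
13-P. edulis "tai nong"	P. edulis	00DDJLFFLLCDCEDF
14-P. edulis "tai nong"	P. edulis	GIDDJJFFLLCDCEDF
15-P. edulis "tai nong"	P. edulis	GIDDJJFFLLCDCEDF
16-P. edulis "zi xiang"	P. edulis	GIDFIIFFKKCDACDF
17-P. edulis "zi xiang"	P. edulis	GIDFJLFFLLCDCEDF
18-P. edulis "zi xiang"	P. edulis	ABFFJLFFLLCDEEDF
19-P. edulis "gui han yi hao"	P. edulis	GGFFJJFFLLDDEEFF
20-P. edulis "gui han yi hao"	P. edulis	FFFFJJFFLLDDEEFF
21-P. edulis "gui han yi hao"	P. edulis	GGFFJJCFLLDDEEFF
22-P. edulis f. flavicarpa "16#"	P. edulis f. flavicarpa	BIDDJJCCLLCCCCDD
23-P. edulis f. flavicarpa "6#"	P. edulis f. flavicarpa	BBDDJJCCLLACACDD
24-P. edulis f. flavicarpa "mi zhuan"	P. edulis f. flavicarpa	EECCIICCMMCCACDF
25-P. edulis f. flavicarpa "qing ren guo"	P. edulis f. flavicarpa	BBDDLLCCLLCCCCDD
26-P. edulis f. flavicarpa (stock)	P. edulis f. flavicarpa	BCEEJJCCLLAACCDD
27-P. edulis f. flavicarpa "9#"	P. edulis f. flavicarpa	BBDDJJCCLLACCCDD
28-P. edulis f. flavicarpa	P. edulis f. flavicarpa	IIDDJLCCLLACCC00
29-P. edulis f. flavicarpa	P. edulis f. flavicarpa	IIDDJLCCLLACCCDD
30-P. trifasciata	P.trifasciata	GI00IJACCDCCCCDD
31-P. wilsonii	P. wilsonii	BI00IJBBLL00CCDD
32-P. xishuangbannaensis	P. xishuangbannaensis	BH0000BBLL00CCDD
33-P. 'Lady Margaret'	P. 'Lady Margaret'	BIACNNCCHLCCACCC
34-P. 'Lady Margaret'	P. 'Lady Margaret'	BGACINCCHLCCACDD
35-P. amethystina	P. amethystina	DGBBGGBBIIDDABAD
36-P. amethystina	P. amethystina	DGBBGGBBIIDDABAA
37-P. caerulea	P. caerulea	DDBBIJBBJJDDBBDD
38-P. incarnata x P. laurifiolia	P. incarnata x P. laurifiolia	BGACMMEELLBCAA00
39-P. incarnata x P. laurifiolia	P. incarnata x P. laurifiolia	EECEIICCLLBDABCC
40-P. incarnata x P. laurifiolia	P. incarnata x P. laurifiolia	EECEOOCCLLBDABCC
41-P. incarnata x P. laurifiolia	P. incarnata x P. laurifiolia	EECEOOCCELBDABCC
42-P. foetida	P. foetida	00BBHHDDNNCCBB00
43-P. foetida	P. foetida	AIBBHHCCNNCCBB00
44-P. foetida	P. foetida	AABBHH00NNCDBBDD
45-P. foetida	P. foetida	GIBBHHGGLNCCBBFF
46-P. foetida	P. foetida	GIBBHH00NNCDBB00
47-P. incarnata	P. incarnata	EECC00EEOOBCACCC
48-P. incarnata	P. incarnata	BBCCHMEEOOBCACCC
49-P. ligularis	P. ligularis	IICCII00MMCCCC00
50-P. ligularis	P. ligularis	IICCIICCMMCCCCDD
51-P. ligularis	P. ligularis	IICCIICCMMCCCC00
52-P. ligularis	P. ligularis	IICCIICCMMCCCCDD
53-P. ligularis	P. ligularis	GIDDJJFFLLCDCEDE
54-P. miniata	P. miniata	BICCIICCEHCCCCDD
55-P. miniata	P. miniata	BICCIICCHHCCCC00
56-P. miniata	P. miniata	BJCCIICCHHCCCC00
57-P. miniata	P. miniata	BBCCIICCHHCCCC00
58-P. miniata	P. miniata	BBCCIICCHHCCCCDD
59-P. miniata	P. miniata	BBCCIICCHHCCCCDD
60-P. miniata	P. miniata	BBCCIICCHHCCCCDD
61-P. miniata	P. miniata	BBCCIICCHHCCCC00
62-P. miniata	P. miniata	BGCCIICCHHCCCC00
63-P. miniata	P. miniata	BBCCIICCHHCCCCDD
64-P. miniata Xishuangbanna Red	P. miniata Xishuangbanna Red	00CCIICCHHCCCCDD
65-P. miniata x P. serrulata	P. miniata x P. serrulata	BHCCIICCHLCDCCDD
66-P. miniata x P. serrulata	P. miniata x P. serrulata	BHCCIICCHLCDCCDD
67-P. miniata x P. serrulata	P. miniata x P. serrulata	BHCCIICCHLCDCCDD
68-P. miniata x P. serrulata	P. miniata x P. serrulata	HHCCIICCHLCDCCDD
69-P. miniata x P. serrulata	P. miniata x P. serrulata	HHCCIICCHLCDCCDD
70-P. miniata x P. serrulata	P. miniata x P. serrulata	BHCCIICCHLCDCCDD
71-P. morifolia	P. morifolia	0000DJBBAACDCCDD
72-P. morifolia	P. morifolia	0000JJBCLLCCCCDD
73-P. morifolia	P. morifolia	0000BBBCBB00CCDD
74-P. quadrangularis	P. quadrangularis	AAFFGGAALLBBDDDD
75-P. quadrangularis	P. quadrangularis	AAFFGGAALLBBDDDD
76-P. quadrangularis	P. quadrangularis	AAFFIIAALLBCDDBD
77-P. serrulata	P. serrulata	HHCCIICCLLDDCCDD
78-P. suberosa	P. suberosa	II00IJ00GLBBCCDG
79-P. suberosa	P. suberosa	00000000GG0000DG
80-P. suberosa	P. suberosa	00000000GG00AC00
81-P. suberosa	P. suberosa	JJ00IJ00GGCCCC00
87-P. suberosa	P. suberosa	AI00DIACGG00CC00
83-P. suberosa	P. suberosa	0000EE00GG00CCGG
84-P. violacea 'victoria'	P. violacea 'victoria'	DI00IIBBLLCCAB00
85-P. violacea 'victoria'	P. violacea 'victoria'	DIBBIIBBLLCCABDD
86-P. yucatanensis	P. yucatanensis	II00BK00DDCDCC00
87-P. yucatanensis	P. yucatanensis	II00FF00DDACCCDD
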