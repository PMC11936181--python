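compound_id,pubchem_cid,anti_inflammatory,excluded_known_anti_oa,gi_absorption,bbb_permeant,pgp_substrate,bioactivity_gpcr,bioactivity_ion_channel,bioactivity_kinase,bioactivity_nuclear_receptor,bioactivity_protease,bioactivity_enzyme,oral_ld50_mg_kg,hepatotoxicity,neurotoxicity,nephrotoxicity,respiratory_toxicity,cardiotoxicity
Rutaecarpine,65752,true,true,,,,,,,,,,,,,,,
Sesamolin,101746,false,false,,,,,,,,,,,,,,,
Corilagin,73568,true,false,Low,No,Yes,-0.11,-0.71,-0.45,-0.44,-0.03,-0.15,2260,-,-,+,+,-
Apigetrin,5280704,true,false,Low,No,Yes,0.10,-0.01,0.14,0.31,0.02,0.43,5000,-,-,+,+,+
Gamabufotalin,259803,false,false,,,,,,,,,,,,,,,
Protopine,4970,true,false,High,Yes,Yes,0.18,-0.04,-0.26,-0.23,-0.03,0.04,940,-,+,-,+,-
5-methoxyflavone,94525,true,false,High,Yes,Yes,-0.18,-0.18,0.04,0.03,-0.37,0.07,4000,-,-,+,+,-
"7,3',4'-trihydroxyisoflavone",5284648,true,false,High,Yes,Yes,-0.24,-0.60,-0.10,0.11,-0.77,0.06,2500,-,-,+,+,-
Viaminate,6438483,false,false,,,,,,,,,,,,,,,
KAN0438757,71586631,false,false,,,,,,,,,,,,,,,
Savinin,5281867,false,false,,,,,,,,,,,,,,,
Maraviroc,3002977,false,false,,,,,,,,,,,,,,,
6-methoxyflavone,147157,false,false,,,,,,,,,,,,,,,
Sargachromenol,10455044,false,false,,,,,,,,,,,,,,,
Tryptanthrin,73549,false,false,,,,,,,,,,,,,,,
Chryseriol,5280666,false,false,,,,,,,,,,,,,,,
Mogrol,14525327,false,false,,,,,,,,,,,,,,,
Nuciferine,10146,false,false,,,,,,,,,,,,,,,
Dehydromiltirone,3082765,false,false,,,,,,,,,,,,,,,
Rosmanol,13966122,false,false,,,,,,,,,,,,,,,
W54011,5311122,false,false,,,,,,,,,,,,,,,
Oxocrebanine,3084713,false,false,,,,,,,,,,,,,,,
Chrysoeriol,5280666,false,false,,,,,,,,,,,,,,,
Matairesinol,119205,false,false,,,,,,,,,,,,,,,
Fluorofenidone,11851183,false,false,,,,,,,,,,,,,,,
Demethoxycurcumin,5469424,false,false,,,,,,,,,,,,,,,
Eupatilin,5273755,false,false,,,,,,,,,,,,,,,
Xanthenone,7020,false,false,,,,,,,,,,,,,,,
Tetrahydropalmatine,72301,false,false,,,,,,,,,,,,,,,
Harmine,5280953,false,false,,,,,,,,,,,,,,,
Isosinensetin,632135,false,false,,,,,,,,,,,,,,,
Xanthotoxol,65090,false,false,,,,,,,,,,,,,,,
Cl-Amidine,24970878,false,false,,,,,,,,,,,,,,,
"3,3',4,5'-tetramethoxy-trans-stilbene",5387294,false,false,,,,,,,,,,,,,,,
Pteryxin,5281425,false,false,,,,,,,,,,,,,,,
6-methylcoumarin,7092,false,false,,,,,,,,,,,,,,,
Ibudilast,3671,false,false,,,,,,,,,,,,,,,
Fingolimod,107970,false,false,,,,,,,,,,,,,,,
Xanthatin,5281511,false,false,,,,,,,,,,,,,,,
Guanosine,135398635,false,false,,,,,,,,,,,,,,,
Nardostachin,196699,false,false,,,,,,,,,,,,,,,
Dehydrozingerone,5354238,false,false,,,,,,,,,,,,,,,
Scopoletin,5280460,false,false,,,,,,,,,,,,,,,
Bicyclol,9821754,false,false,,,,,,,,,,,,,,,
Nicorandil,47528,false,false,,,,,,,,,,,,,,,
Pramipexole,119570,false,false,,,,,,,,,,,,,,,
"2,4-dimethoxy-6-methylbenzene-1,3-diol",87294508,false,false,,,,,,,,,,,,,,,
Hordenine,68313,false,false,,,,,,,,,,,,,,,
Ergothioneine,5351619,false,false,,,,,,,,,,,,,,,
Dencichine,440259,false,false,,,,,,,,,,,,,,,
BML-111,10899465,false,false,,,,,,,,,,,,,,,
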