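# Isotopic masses (Da) and abundances, CODATA/IUPAC-CIAAW 2013 representative values.
# Pinned in-repo so mass calculations are bit-stable across environments.
element,nominal,mass,abundance
H,1,1.00782503207,0.999885
H,2,2.01410177785,0.000115
C,12,12.0000000000,0.9893
C,13,13.00335483507,0.0107
N,14,14.00307400443,0.99636
N,15,15.00010889888,0.00364
O,16,15.99491461957,0.99757
O,17,16.99913175650,0.00038
O,18,17.99915961286,0.00205
S,32,31.97207117744,0.9499
S,33,32.97145890982,0.0075
S,34,33.96786700447,0.0425
S,36,35.96708071,0.0001
Cu,63,62.92959772,0.6915
Cu,65,64.92778970,0.3085
Zn,64,63.92914201,0.4917
Zn,66,65.92603381,0.2773
Zn,67,66.92712775,0.0404
Zn,68,67.92484455,0.1845
Zn,70,69.9253192,0.0061
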