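drug,class,cases,ror,ci_low,ci_high,ic,ic025
methotrexate,conventional DMARDs,848,3.80,3.53,4.08,1.77,1.66
leflunomide,conventional DMARDs,169,2.85,2.44,3.32,1.48,1.22
sulfasalazine,conventional DMARDs,44,3.71,2.76,4.99,1.84,1.34
hydroxychloroquine,conventional DMARDs,68,2.17,1.71,2.75,1.09,0.69
azathioprine,conventional DMARDs,10,0.97,0.52,1.81,-0.04,-1.11
cyclosporine,conventional DMARDs,50,0.57,0.43,0.75,-0.81,-1.28
mycophenolate mofetil,conventional DMARDs,97,1.35,1.10,1.64,0.42,0.08
cyclophosphamide,conventional DMARDs,59,1.40,1.08,1.81,0.47,0.04
penicillamine,conventional DMARDs,1,1.92,0.27,13.65,0.56,-3.23
sodium aurothiomalate,conventional DMARDs,0,,,,-0.05,-10.38
auranofin,conventional DMARDs,0,,,,-0.10,-10.42
adalimumab,TNF-α-targeted inhibitors,809,0.79,0.73,0.85,-0.29,-0.41
etanercept,TNF-α-targeted inhibitors,729,1.00,0.93,1.08,0.00,-0.12
infliximab,TNF-α-targeted inhibitors,279,0.77,0.69,0.87,-0.35,-0.55
golimumab,TNF-α-targeted inhibitors,71,1.29,1.02,1.63,0.36,-0.03
certolizumab pegol,TNF-α-targeted inhibitors,109,1.06,0.88,1.28,0.09,-0.23
belimumab,B-cell inhibitors,10,0.30,0.16,0.56,-1.68,-2.75
rituximab,B-cell inhibitors,583,2.81,2.58,3.06,1.40,1.26
anakinra,interleukin inhibitors,7,0.45,0.21,0.94,-1.11,-2.41
canakinumab,interleukin inhibitors,3,0.22,0.07,0.67,-2.03,-4.10
guselkumab,interleukin inhibitors,3,0.15,0.05,0.46,-2.57,-4.63
ixekizumab,interleukin inhibitors,3,0.11,0.04,0.35,-2.93,-5.00
risankizumab,interleukin inhibitors,28,0.62,0.43,0.90,-0.68,-1.31
sarilumab,interleukin inhibitors,7,0.46,0.22,0.96,-1.07,-2.37
secukinumab,interleukin inhibitors,76,0.38,0.31,0.48,-1.34,-1.72
tocilizumab,interleukin inhibitors,237,2.01,1.76,2.29,0.98,0.76
ustekinumab,interleukin inhibitors,42,0.52,0.39,0.71,-0.92,-1.43
tildrakizumab,interleukin inhibitors,0,,,,-1.20,-11.53
brodalumab,interleukin inhibitors,0,,,,-2.25,-12.58
abatacept,T-cell inhibitors,269,2.21,1.96,2.50,1.11,0.90
upadacitinib,JAK inhibitors,87,1.64,1.33,2.03,0.70,0.35
baricitinib,JAK inhibitors,11,1.90,1.05,3.44,0.87,-0.15
tofacitinib,JAK inhibitors,161,0.86,0.73,1.00,-0.21,-0.47
iguratimod,JAK inhibitors,0,,,,-0.01,-10.33
filgotinib,JAK inhibitors,0,,,,-0.02,-10.34
apremilast,PDE4-targeted inhibitor,19,0.14,0.09,0.22,-2.76,-3.53
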