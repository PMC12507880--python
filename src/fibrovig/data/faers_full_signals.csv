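drug,class,cases,ror,ci_low,ci_high,ic,ic025
methotrexate,conventional DMARDs,848,5.43,5.07,5.82,2.38,2.27
leflunomide,conventional DMARDs,169,4.31,3.70,5.01,2.08,1.83
sulfasalazine,conventional DMARDs,44,5.65,4.20,7.60,2.42,1.92
hydroxychloroquine,conventional DMARDs,68,3.30,2.60,4.19,1.69,1.29
azathioprine,conventional DMARDs,10,1.49,0.80,2.77,0.54,-0.54
cyclosporine,conventional DMARDs,50,0.87,0.66,1.15,-0.20,-0.67
mycophenolate mofetil,conventional DMARDs,97,2.05,1.68,2.51,1.03,0.69
cyclophosphamide,conventional DMARDs,59,2.13,1.65,2.76,1.08,0.65
penicillamine,conventional DMARDs,1,1.92,0.27,13.65,0.56,-3.23
sodium aurothiomalate,conventional DMARDs,0,,,,-0.05,-10.38
auranofin,conventional DMARDs,0,,,,-0.10,-10.42
adalimumab,TNF-α-targeted inhibitors,809,1.26,1.18,1.35,0.32,0.21
etanercept,TNF-α-targeted inhibitors,729,1.55,1.44,1.67,0.61,0.49
infliximab,TNF-α-targeted inhibitors,279,1.20,1.07,1.35,0.26,0.06
golimumab,TNF-α-targeted inhibitors,71,1.97,1.56,2.49,0.97,0.57
certolizumab pegol,TNF-α-targeted inhibitors,109,1.63,1.35,1.96,0.69,0.38
belimumab,B-cell inhibitors,10,0.46,0.25,0.86,-1.07,-2.15
rituximab,B-cell inhibitors,583,4.14,3.82,4.50,2.01,1.87
anakinra,interleukin inhibitors,7,0.68,0.33,1.43,-0.52,-1.82
canakinumab,interleukin inhibitors,3,0.33,0.11,1.03,-1.44,-3.51
guselkumab,interleukin inhibitors,3,0.23,0.07,0.70,-1.97,-4.04
ixekizumab,interleukin inhibitors,3,0.17,0.06,0.54,-2.33,-4.40
risankizumab,interleukin inhibitors,28,0.95,0.66,1.38,-0.07,-0.70
sarilumab,interleukin inhibitors,7,0.70,0.33,1.47,-0.48,-1.79
secukinumab,interleukin inhibitors,76,0.60,0.48,0.75,-0.73,-1.11
tocilizumab,interleukin inhibitors,237,3.04,2.67,3.46,1.58,1.37
ustekinumab,interleukin inhibitors,42,0.81,0.59,1.09,-0.31,-0.82
tildrakizumab,interleukin inhibitors,0,,,,-1.20,-11.53
brodalumab,interleukin inhibitors,0,,,,-2.25,-12.58
abatacept,T-cell inhibitors,269,3.33,2.96,3.76,1.71,1.51
upadacitinib,JAK inhibitors,87,2.51,2.03,3.09,1.31,0.95
baricitinib,JAK inhibitors,11,2.90,1.61,5.25,1.42,0.40
tofacitinib,JAK inhibitors,161,1.32,1.13,1.54,0.40,0.14
iguratimod,JAK inhibitors,0,,,,-0.01,-10.33
filgotinib,JAK inhibitors,0,,,,-0.02,-10.34
apremilast,PDE4-targeted inhibitor,19,0.22,0.14,0.34,-2.15,-2.92
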