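drug,class,cases,ror,ci_low,ci_high,ic,ic025
methotrexate,conventional DMARDs,1097,4.39,4.11,4.70,1.85,1.75
leflunomide,conventional DMARDs,138,3.26,2.75,3.86,1.66,1.38
sulfasalazine,conventional DMARDs,101,2.33,1.91,2.84,1.19,0.86
hydroxychloroquine,conventional DMARDs,66,1.14,0.90,1.46,0.19,-0.22
azathioprine,conventional DMARDs,63,1.20,0.93,1.54,0.25,-0.16
cyclosporine,conventional DMARDs,40,0.38,0.28,0.52,-1.35,-1.87
mycophenolate mofetil,conventional DMARDs,121,1.11,0.93,1.33,0.15,-0.15
cyclophosphamide,conventional DMARDs,244,1.11,0.98,1.27,0.15,-0.07
penicillamine,conventional DMARDs,31,5.67,3.98,8.08,2.38,1.79
sodium aurothiomalate,conventional DMARDs,42,13.87,10.20,18.84,3.56,3.04
auranofin,conventional DMARDs,10,2.90,1.56,5.40,1.41,0.33
adalimumab,TNF-α-targeted inhibitors,782,0.67,0.62,0.73,-0.46,-0.58
etanercept,TNF-α-targeted inhibitors,663,0.77,0.71,0.84,-0.31,-0.44
infliximab,TNF-α-targeted inhibitors,319,1.12,1.00,1.25,0.15,-0.03
golimumab,TNF-α-targeted inhibitors,50,0.62,0.47,0.82,-0.67,-1.14
certolizumab pegol,TNF-α-targeted inhibitors,72,0.59,0.47,0.75,-0.73,-1.13
belimumab,B-cell inhibitors,9,0.28,0.15,0.54,-1.76,-2.90
rituximab,B-cell inhibitors,287,1.43,1.27,1.61,0.49,0.29
anakinra,interleukin inhibitors,13,0.89,0.52,1.53,-0.16,-1.10
canakinumab,interleukin inhibitors,4,0.33,0.12,0.88,-1.48,-3.25
guselkumab,interleukin inhibitors,4,0.11,0.04,0.29,-3.06,-4.82
ixekizumab,interleukin inhibitors,8,0.13,0.07,0.27,-2.80,-4.01
risankizumab,interleukin inhibitors,40,0.54,0.40,0.74,-0.87,-1.40
sarilumab,interleukin inhibitors,8,0.35,0.18,0.70,-1.45,-2.66
secukinumab,interleukin inhibitors,37,0.17,0.13,0.24,-2.45,-3.00
tocilizumab,interleukin inhibitors,142,1.28,1.08,1.51,0.35,0.07
ustekinumab,interleukin inhibitors,34,0.29,0.21,0.40,-1.75,-2.32
tildrakizumab,interleukin inhibitors,0,,,,-2.77,-13.10
brodalumab,interleukin inhibitors,1,0.23,0.03,1.66,-1.67,-5.45
abatacept,T-cell inhibitors,145,1.15,0.98,1.36,0.20,-0.08
upadacitinib,JAK inhibitors,92,1.07,0.87,1.31,0.09,-0.25
baricitinib,JAK inhibitors,21,0.71,0.46,1.10,-0.47,-1.21
tofacitinib,JAK inhibitors,142,0.71,0.60,0.84,-0.47,-0.75
iguratimod,JAK inhibitors,0,,,,-2.07,-12.39
filgotinib,JAK inhibitors,2,0.79,0.20,3.15,-0.28,-2.88
apremilast,PDE4-targeted inhibitor,19,0.10,0.07,0.16,-3.19,-3.96
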