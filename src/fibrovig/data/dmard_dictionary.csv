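generic,class,synonyms
methotrexate,conventional DMARDs,Trexall|Otrexup|Rasuvo|Rheumatrex|amethopterin
leflunomide,conventional DMARDs,Arava
sulfasalazine,conventional DMARDs,Azulfidine|Salazopyrin|sulphasalazine
hydroxychloroquine,conventional DMARDs,Plaquenil
azathioprine,conventional DMARDs,Imuran|Azasan
cyclosporine,conventional DMARDs,Neoral|Sandimmune|ciclosporin
mycophenolate mofetil,conventional DMARDs,CellCept
cyclophosphamide,conventional DMARDs,Cytoxan|Endoxan
penicillamine,conventional DMARDs,Cuprimine|Depen
sodium aurothiomalate,conventional DMARDs,Myochrysine|gold sodium thiomalate
auranofin,conventional DMARDs,Ridaura
etanercept,TNF-α-targeted inhibitors,Benepali|Enbrel|Erelzi|Eticovo|Nepexto
infliximab,TNF-α-targeted inhibitors,Remicade|Inflectra|Renflexis|Avsola
adalimumab,TNF-α-targeted inhibitors,Humira|Amjevita|Hyrimoz|Cyltezo
golimumab,TNF-α-targeted inhibitors,Simponi
certolizumab pegol,TNF-α-targeted inhibitors,Cimzia
belimumab,B-cell inhibitors,Benlysta
rituximab,B-cell inhibitors,Rituxan|MabThera|Truxima|Ruxience
abatacept,T-cell inhibitors,Orencia
anakinra,interleukin inhibitors,Kineret
canakinumab,interleukin inhibitors,Ilaris
guselkumab,interleukin inhibitors,Tremfya
ixekizumab,interleukin inhibitors,Taltz
risankizumab,interleukin inhibitors,Skyrizi
sarilumab,interleukin inhibitors,Kevzara
secukinumab,interleukin inhibitors,Cosentyx
tocilizumab,interleukin inhibitors,Actemra|RoActemra
ustekinumab,interleukin inhibitors,Stelara
tildrakizumab,interleukin inhibitors,Ilumya|Ilumetri
brodalumab,interleukin inhibitors,Siliq|Kyntheum
tofacitinib,JAK inhibitors,Xeljanz
baricitinib,JAK inhibitors,Olumiant
upadacitinib,JAK inhibitors,Rinvoq
iguratimod,JAK inhibitors,Careram|Kolbet
filgotinib,JAK inhibitors,Jyseleca
apremilast,PDE4-targeted inhibitor,Otezla
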