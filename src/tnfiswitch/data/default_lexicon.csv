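pattern,canonical,name_kind
adalimumab,adalimumab,generic
humira,adalimumab,brand
etanercept,etanercept,generic
enbrel,etanercept,brand
certolizumab,certolizumab,generic
certolizumab pegol,certolizumab,generic
cimzia,certolizumab,brand
golimumab,golimumab,generic
simponi,golimumab,brand
infliximab,infliximab-biooriginator,generic
remicade,infliximab-biooriginator,brand
infliximab-dyyb,infliximab-biosimilar,biosimilar
inflectra,infliximab-biosimilar,biosimilar
infliximab-abda,infliximab-biosimilar,biosimilar
renflexis,infliximab-biosimilar,biosimilar
infliximab-axxq,infliximab-biosimilar,biosimilar
avsola,infliximab-biosimilar,biosimilar
infliximab-qbtx,infliximab-biosimilar,biosimilar
ixifi,infliximab-biosimilar,biosimilar
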