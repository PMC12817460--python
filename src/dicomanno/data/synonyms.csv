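term,snomed_code
BAUCH,818983003
ABD,818983003
ARM,120574008
UPPER EXTREMITY,120574008
OBERE EXTREMITAET,120574008
OBERARM,120574008
HUMERUS,120574008
MITTELHAND,85562004
ELLENBOGEN,127949000
ELLBOGEN,127949000
HANDGELENK,8205005
PHALANX,7569003
THUMB,76505004
POLLEX,76505004
AC JOINT,85856004
ACROMIOCLAVICULAR JOINT,85856004
SCHULTERECKGELENK,85856004
SCHULTER,16982005
FOREARM,14975008
VORDERARM,14975008
RADIUS,14975008
BECKEN,12921003
FEMUR,302524008
OBERSCHENKEL,302524008
DISTAL FEMUR,302524008
KNIE,72696002
KNEE JOINT,72696002
FUSS,56459004
VORFUSS,56459004
HUEFTE,29836001
HUEFTGELENK,29836001
HIP JOINT,29836001
TOE,29707007
ZEHE,29707007
SPRUNGGELENK,344001
OSG,344001
KNIESCHEIBE,64234005
LEG,120575009
BEIN,120575009
LOWER EXTREMITY,120575009
UNTERE EXTREMITAET,120575009
UNTERSCHENKEL,120575009
MAMMA,76752008
BRUST,76752008
SKULL,89546000
HEAD,89546000
SCHAEDEL,89546000
CRANIUM,89546000
NOSE,45206002
NASENBEIN,45206002
MANDIBLE,91609006
UNTERKIEFER,91609006
KIEFER,91609006
THORAX,51185008
LUNGE,51185008
RIPPEN,113197003
RIPPE,113197003
HWS,122494005
CERVICAL SPINE,122494005
HALSWIRBELSAEULE,122494005
LWS,122496007
LUMBAR SPINE,122496007
LENDENWIRBELSAEULE,122496007
THORAKOLUMBAL,264232007
TL SPINE,264232007
BWS,122495006
THORACIC SPINE,122495006
BRUSTWIRBELSAEULE,122495006
WIRBELSAEULE,51282000
SPINE,51282000
WHOLE SPINE,51282000
SCHLUESSELBEIN,51299004
KLAVIKULA,51299004
SACRUM,54735007
SAKRUM,54735007
BRUSTBEIN,56873002
BERICHT,-2
BEFUND,-2
DOSE REPORT,-2
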