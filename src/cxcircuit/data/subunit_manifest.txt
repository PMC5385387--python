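# canonical subunit manifest: 154 subunits, block order fixed
# PB (16)
PB R8
PB R7
PB R6
PB R5
PB R4
PB R3
PB R2
PB R1
PB L1
PB L2
PB L3
PB L4
PB L5
PB L6
PB L7
PB L8
# FB.a (8)
FB.a R4
FB.a R3
FB.a R2
FB.a R1
FB.a L1
FB.a L2
FB.a L3
FB.a L4
# FB.b (8)
FB.b R4
FB.b R3
FB.b R2
FB.b R1
FB.b L1
FB.b L2
FB.b L3
FB.b L4
# FB.c (8)
FB.c R4
FB.c R3
FB.c R2
FB.c R1
FB.c L1
FB.c L2
FB.c L3
FB.c L4
# FB.d (8)
FB.d R4
FB.d R3
FB.d R2
FB.d R1
FB.d L1
FB.d L2
FB.d L3
FB.d L4
# FB.e (8)
FB.e R4
FB.e R3
FB.e R2
FB.e R1
FB.e L1
FB.e L2
FB.e L3
FB.e L4
# FB.f (8)
FB.f R4
FB.f R3
FB.f R2
FB.f R1
FB.f L1
FB.f L2
FB.f L3
FB.f L4
# EB.A (16)
EB.A R8
EB.A R7
EB.A R6
EB.A R5
EB.A R4
EB.A R3
EB.A R2
EB.A R1
EB.A L1
EB.A L2
EB.A L3
EB.A L4
EB.A L5
EB.A L6
EB.A L7
EB.A L8
# EB.O (16)
EB.O R8
EB.O R7
EB.O R6
EB.O R5
EB.O R4
EB.O R3
EB.O R2
EB.O R1
EB.O L1
EB.O L2
EB.O L3
EB.O L4
EB.O L5
EB.O L6
EB.O L7
EB.O L8
# EB.C (16)
EB.C R8
EB.C R7
EB.C R6
EB.C R5
EB.C R4
EB.C R3
EB.C R2
EB.C R1
EB.C L1
EB.C L2
EB.C L3
EB.C L4
EB.C L5
EB.C L6
EB.C L7
EB.C L8
# EB.P (16)
EB.P R8
EB.P R7
EB.P R6
EB.P R5
EB.P R4
EB.P R3
EB.P R2
EB.P R1
EB.P L1
EB.P L2
EB.P L3
EB.P L4
EB.P L5
EB.P L6
EB.P L7
EB.P L8
# NO (8)
NO L1
NO L2
NO L3
NO L4
NO R1
NO R2
NO R3
NO R4
# IDFP (10)
IDFP HBm-L
IDFP HBl-L
IDFP DSB-L
IDFP VSB-L
IDFP RB-L
IDFP HBm-R
IDFP HBl-R
IDFP DSB-R
IDFP VSB-R
IDFP RB-R
# CCP (2)
CCP L
CCP R
# CVLP (2)
CVLP L
CVLP R
# VMP (4)
VMP d-L
VMP v-L
VMP d-R
VMP v-R
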