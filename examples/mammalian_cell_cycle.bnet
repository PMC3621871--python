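targets, factors
CycD, CycD
Rb, (!CycD & !CycE & !CycA & !CycB) | (p27 & !CycD & !CycB)
E2F, (!Rb & !CycA & !CycB) | (p27 & !Rb & !CycB)
CycE, E2F & !Rb
CycA, (E2F & !Rb & !Cdc20 & !(Cdh1 & UbcH10)) | (CycA & !Rb & !Cdc20 & !(Cdh1 & UbcH10))
p27, (!CycD & !CycE & !CycA & !CycB) | (p27 & !(CycE & CycA) & !CycB & !CycD)
Cdc20, CycB
Cdh1, (!CycA & !CycB) | Cdc20 | (p27 & !CycB)
UbcH10, !Cdh1 | (Cdh1 & UbcH10 & (Cdc20 | CycA | CycB))
CycB, !Cdc20 & !Cdh1
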