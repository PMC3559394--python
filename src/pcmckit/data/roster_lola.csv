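id,name,sex,age_years,age_class,rearing,mother_id,group_id
OP,Opala,F,16,adult,orphan,,g1
SW,Semendwa,F,14,adult,orphan,,g1
BD,Bandundu,F,14,adult,orphan,,g1
KL,Kalina,F,13,adult,orphan,,g1
SL,Salonga,F,13,adult,orphan,,g1
KS,Kisantu,F,12,adult,orphan,,g1
LS,Lisala,F,10,adolescent,orphan,,g1
KT,Katako,F,7,juvenile,orphan,,g1
EK,Elikia,F,6,juvenile,mother_reared,SW,g1
MS,Masisi,F,5,juvenile,orphan,,g1
WK,Waka,F,5,juvenile,orphan,,g1
ML,Malaika,F,4,juvenile,mother_reared,KL,g1
MN,Manono,M,17,adult,orphan,,g1
KW,Kikwit,M,13,adult,orphan,,g1
FZ,Fizi,M,12,adult,orphan,,g1
MA,Matadi,M,11,adolescent,orphan,,g1
DL,Dilolo,M,10,adolescent,orphan,,g1
KG,Kasongo,M,9,adolescent,orphan,,g1
MB,Mabali,M,8,adolescent,orphan,,g1
PO,Pole,M,6,juvenile,mother_reared,OP,g1
WO,Wongolo,M,3,juvenile,mother_reared,BD,g1
Makasi,Makasi,M,1,infant,mother_reared,SW,g1
Bolingo,Bolingo,M,1,infant,mother_reared,KL,g1
Kimia,Kimia,F,1,infant,mother_reared,SL,g1
Liyaka,Liyaka,F,1,infant,mother_reared,KS,g1
MY,Maya,F,18,adult,orphan,,g2
TL,Tshilomba,F,20,adult,orphan,,g2
IS,Isiro,F,13,adult,orphan,,g2
LI,Likasi,F,10,adolescent,orphan,,g2
SK,Sake,F,6,juvenile,orphan,,g2
KZ,Keza,M,20,adult,orphan,,g2
MK,Makali,M,20,adult,orphan,,g2
MX,Max,M,25,adult,orphan,,g2
LM,Lomami,M,12,adult,orphan,,g2
MB2,Mbandaka,M,9,adolescent,orphan,,g2
BL,Bili,M,10,adolescent,orphan,,g2
IB,Ilebo,M,9,adolescent,orphan,,g2
YL,Yolo,M,7,adolescent,orphan,,g2
BS,Bisengo,M,6,juvenile,mother_reared,MY,g2
MO,Moyi,M,4,juvenile,mother_reared,TL,g2
Mayele,Mayele,M,1,infant,mother_reared,MY,g2
Sanza,Sanza,M,1,infant,mother_reared,TL,g2
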