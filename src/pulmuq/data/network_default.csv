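name,length_cm,radius_cm,side,parent,daughter1,daughter2,terminal_partner
MPA,4.30,1.350,arterial,,LPA,RPA,
LPA,2.50,0.900,arterial,MPA,LIA,LSA,
RPA,5.75,1.100,arterial,MPA,RIA,RSA,
LIA,2.15,0.842,arterial,LPA,LIA D1,LIA D2,
LSA,1.23,0.481,arterial,LPA,LSA D1,LSA D2,
RIA,2.35,0.922,arterial,RPA,RIA D1,RIA D2,
RSA,1.92,0.755,arterial,RPA,RSA D1,RSA D2,
LIA D1,1.93,0.757,arterial,LIA,,,LIV D1
LIA D2,1.31,0.514,arterial,LIA,,,LIV D2
LSA D1,1.10,0.433,arterial,LSA,,,LSV D1
LSA D2,0.75,0.293,arterial,LSA,,,LSV D2
RIA D1,2.11,0.829,arterial,RIA,,,RIV D1
RIA D2,1.43,0.562,arterial,RIA,,,RIV D2
RSA D1,1.17,0.460,arterial,RSA,,,RSV D1
RSA D2,1.55,0.610,arterial,RSA,,,RSV D2
LIV,2.15,0.641,venous,,LIV D1,LIV D2,
LSV,1.23,0.716,venous,,LSV D1,LSV D2,
RIV,2.35,0.864,venous,,RIV D1,RIV D2,
RSV,1.92,0.824,venous,,RSV D1,RSV D2,
LIV D1,1.93,0.576,venous,LIV,,,LIA D1
LIV D2,1.31,0.391,venous,LIV,,,LIA D2
LSV D1,1.10,0.643,venous,LSV,,,LSA D1
LSV D2,0.75,0.436,venous,LSV,,,LSA D2
RIV D1,2.11,0.777,venous,RIV,,,RIA D1
RIV D2,1.43,0.527,venous,RIV,,,RIA D2
RSV D1,1.73,0.740,venous,RSV,,,RSA D1
RSV D2,1.17,0.502,venous,RSV,,,RSA D2
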