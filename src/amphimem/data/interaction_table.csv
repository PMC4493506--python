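type_a,type_b,epsilon,sigma
Qda,Qda,5.6,0.47
Qda,Qd,5.6,0.47
Qda,Qa,5.6,0.47
Qda,Q0,4.5,0.47
Qda,P5,5.6,0.47
Qda,P4,5.6,0.47
Qda,P3,5.6,0.47
Qda,P2,5.0,0.47
Qda,P1,5.0,0.47
Qda,Nda,5.0,0.47
Qda,Nd,5.0,0.47
Qda,Na,5.0,0.47
Qda,N0,3.5,0.47
Qda,C5,3.1,0.47
Qda,C4,2.7,0.47
Qda,C3,2.3,0.47
Qda,C2,2.0,0.62
Qda,C1,2.0,0.62
Qd,Qd,5.0,0.47
Qd,Qa,5.6,0.47
Qd,Q0,4.5,0.47
Qd,P5,5.6,0.47
Qd,P4,5.6,0.47
Qd,P3,5.6,0.47
Qd,P2,5.0,0.47
Qd,P1,5.0,0.47
Qd,Nda,5.0,0.47
Qd,Nd,4.0,0.47
Qd,Na,5.0,0.47
Qd,N0,3.5,0.47
Qd,C5,3.1,0.47
Qd,C4,2.7,0.47
Qd,C3,2.3,0.47
Qd,C2,2.0,0.62
Qd,C1,2.0,0.62
Qa,Qa,5.0,0.47
Qa,Q0,4.5,0.47
Qa,P5,5.6,0.47
Qa,P4,5.6,0.47
Qa,P3,5.6,0.47
Qa,P2,5.0,0.47
Qa,P1,5.0,0.47
Qa,Nda,5.0,0.47
Qa,Nd,5.0,0.47
Qa,Na,4.0,0.47
Qa,N0,3.5,0.47
Qa,C5,3.1,0.47
Qa,C4,2.7,0.47
Qa,C3,2.3,0.47
Qa,C2,2.0,0.62
Qa,C1,2.0,0.62
Q0,Q0,3.5,0.47
Q0,P5,5.0,0.47
Q0,P4,5.6,0.47
Q0,P3,5.0,0.47
Q0,P2,4.5,0.47
Q0,P1,4.0,0.47
Q0,Nda,4.0,0.47
Q0,Nd,4.0,0.47
Q0,Na,4.0,0.47
Q0,N0,3.5,0.47
Q0,C5,3.1,0.47
Q0,C4,2.7,0.47
Q0,C3,2.3,0.47
Q0,C2,2.0,0.62
Q0,C1,2.0,0.62
P5,P5,5.6,0.47
P5,P4,5.6,0.47
P5,P3,5.6,0.47
P5,P2,5.6,0.47
P5,P1,5.6,0.47
P5,Nda,5.0,0.47
P5,Nd,5.0,0.47
P5,Na,5.0,0.47
P5,N0,3.5,0.47
P5,C5,3.1,0.47
P5,C4,2.7,0.47
P5,C3,2.7,0.47
P5,C2,2.3,0.47
P5,C1,2.0,0.47
P4,P4,5.0,0.47
P4,P3,5.0,0.47
P4,P2,4.5,0.47
P4,P1,4.5,0.47
P4,Nda,4.0,0.47
P4,Nd,4.0,0.47
P4,Na,4.0,0.47
P4,N0,3.5,0.47
P4,C5,3.1,0.47
P4,C4,2.7,0.47
P4,C3,2.7,0.47
P4,C2,2.3,0.47
P4,C1,2.0,0.47
P3,P3,5.0,0.47
P3,P2,4.5,0.47
P3,P1,4.5,0.47
P3,Nda,4.5,0.47
P3,Nd,4.5,0.47
P3,Na,4.5,0.47
P3,N0,3.5,0.47
P3,C5,3.5,0.47
P3,C4,3.1,0.47
P3,C3,2.7,0.47
P3,C2,2.7,0.47
P3,C1,2.3,0.47
P2,P2,4.5,0.47
P2,P1,4.5,0.47
P2,Nda,4.5,0.47
P2,Nd,4.5,0.47
P2,Na,4.5,0.47
P2,N0,4.0,0.47
P2,C5,3.5,0.47
P2,C4,3.5,0.47
P2,C3,3.1,0.47
P2,C2,2.7,0.47
P2,C1,2.3,0.47
P1,P1,4.5,0.47
P1,Nda,4.5,0.47
P1,Nd,4.5,0.47
P1,Na,4.5,0.47
P1,N0,4.0,0.47
P1,C5,3.5,0.47
P1,C4,3.5,0.47
P1,C3,3.5,0.47
P1,C2,3.1,0.47
P1,C1,2.7,0.47
Nda,Nda,4.5,0.47
Nda,Nd,4.5,0.47
Nda,Na,4.5,0.47
Nda,N0,3.5,0.47
Nda,C5,3.5,0.47
Nda,C4,3.1,0.47
Nda,C3,2.7,0.47
Nda,C2,2.7,0.47
Nda,C1,2.7,0.47
Nd,Nd,4.0,0.47
Nd,Na,4.5,0.47
Nd,N0,3.5,0.47
Nd,C5,3.5,0.47
Nd,C4,3.1,0.47
Nd,C3,2.7,0.47
Nd,C2,2.7,0.47
Nd,C1,2.7,0.47
Na,Na,4.0,0.47
Na,N0,3.5,0.47
Na,C5,3.5,0.47
Na,C4,3.1,0.47
Na,C3,2.7,0.47
Na,C2,2.7,0.47
Na,C1,2.7,0.47
N0,N0,3.5,0.47
N0,C5,3.5,0.47
N0,C4,3.5,0.47
N0,C3,3.5,0.47
N0,C2,3.1,0.47
N0,C1,2.7,0.47
C5,C5,3.5,0.47
C5,C4,3.5,0.47
C5,C3,3.5,0.47
C5,C2,3.1,0.47
C5,C1,3.1,0.47
C4,C4,3.5,0.47
C4,C3,3.5,0.47
C4,C2,3.1,0.47
C4,C1,3.1,0.47
C3,C3,3.5,0.47
C3,C2,3.5,0.47
C3,C1,3.5,0.47
C2,C2,3.5,0.47
C2,C1,3.5,0.47
C1,C1,3.5,0.47
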