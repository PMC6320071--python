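protein,mutation,unfolding_energy_kbt,unfolding_energy_sem_kbt,equilibrium_force_pn,equilibrium_force_sem_pn,folding_rate_per_s,unfolding_rate_per_s,syntaxin_prob,template_formation_prob,n_fec,snap25_binding_prob,n_binding
,WT,5.2,0.1,5.1,0.1,132,0.7,0.4,0.5,346,0.7,50
Munc18-1,L247R,1.6,0.3,2.3,0.1,,,0.3,0.3,99,0.7,6
Munc18-1,T248G,2.9,0.2,3.1,0.1,,,0,0.3,155,0.3,16
Munc18-1,L247A/T248G,<1.5,,,,,,0,0,241,,
Munc18-1,S306D,5.8,0.1,5.6,0.1,184,0.6,0.4,0.9,123,0.9,53
Munc18-1,L307R,4.1,0.2,4.6,0.1,,,0.07,0.43,114,0.58,19
Munc18-1,S313D,6.1,0.2,5.7,0.1,568,1.5,0.4,1,162,0.8,70
Munc18-1,D324-339,<1.5,,,,,,0,0,105,0,0
Munc18-1,D326K,6.5,0.2,5.7,0.1,420,0.6,0.03,0.9,103,1,27
Munc18-1,P335A,6.0,0.3,5.9,0.1,258,0.5,0.02,0.7,155,0.9,11
Munc18-1,P335L,4.3,0.1,4.8,0.1,17,0.2,0.4,0.3,224,0.8,36
Munc18-1,L341P,<1.5,,,,,,0.06,0.04,176,0.5,4
Munc18-1,L348R,<1.5,,,,,,0.02,0.04,222,0.7,6
Munc18-1,Y473D,4.0,0.1,4.3,0.2,,,0,0.1,395,0.5,24
VAMP2,L32G/Q33G,3.4,0.2,3.9,0.1,310,10,0.4,0.6,170,0.06,33
VAMP2,V39D,3.8,0.4,3.9,0.2,90,2,0.3,0.1,175,0.8,13
VAMP2,M46A,5.2,0.4,5.1,0.2,130,0.7,0.3,0.5,52,0.8,13
VAMP2,E62T,4.1,0.2,4.8,0.2,107,5,0.4,0.5,104,0.4,23
VAMP2,S61D/E62T,3.6,0.2,4.1,0.1,,,0.4,0.7,56,0.2,12
VAMP2,Q76A,4.7,0.2,4.8,0.1,166,2,0.4,0.6,62,0.3,12
VAMP2,F77A,1.5,0.3,2.3,,,,0.5,0.1,121,0.5,6
VAMP2,A81G/A82G,5.0,0.3,4.9,0.2,130,0.8,0.4,0.5,149,0.4,42
VAMP2,D85-94,5.1,0.2,5.0,0.1,120,0.7,0.4,0.5,87,0.7,29
Syntaxin-1,DNRD,<1.5,,,,,,0,0.08,105,0.2,12
Syntaxin-1,DN-peptide,3.2,0.2,4.6,0.1,42,2,0.03,0.5,328,0.4,46
Syntaxin-1,DHabc,<1.5,,,,,,0,0.06,140,0.5,4
Syntaxin-1,L165A/E166A,6.7,0.2,6.1,0.1,406,0.5,0.07,0.7,83,0.9,26
Syntaxin-1,LE/E76K,6.4,0.2,6.0,0.2,123,0.2,0.07,0.9,81,0.7,30
Syntaxin-1,I202G/I203G,3.0,0.3,3.8,0.1,240,12,0.4,0.5,177,0.4,33
Syntaxin-1,F216A,3.7,0.1,5.1,0.1,82,2,0,0.6,155,0.9,32
Syntaxin-1,I230G/D231G/R232G,3.6,0.2,4.3,0.1,,,0,0.5,111,0.4,7
Syntaxin-1,I233G/E234G/Y235G,3.0,0.2,4.1,0.1,,,0,0.6,122,0.7,30
Syntaxin-1,V237G/E238G/H239G,5.2,0.2,4.9,0.1,124,0.7,0.01,0.3,182,0.4,14
Syntaxin-1,T251G/K252G,5.2,0.1,4.9,0.1,126,0.7,0.5,0.8,197,0.7,47
Syntaxin-1,D255-264,5.4,0.2,5.1,0.1,140,0.6,0.5,0.5,134,0.7,29
Syntaxin-1/Munc18-1,LE/D326K,6.6,0.2,6.2,0.1,72,0.1,0.2,0.9,85,0.2,11
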