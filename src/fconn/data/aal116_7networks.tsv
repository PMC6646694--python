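region	network
PreCG.L	sensory-motor
PreCG.R	sensory-motor
SFGdor.L	attention
SFGdor.R	attention
ORBsup.L	default-mode
ORBsup.R	default-mode
MFG.L	attention
MFG.R	attention
ORBmid.L	default-mode
ORBmid.R	default-mode
IFGoperc.L	attention
IFGoperc.R	attention
IFGtriang.L	attention
IFGtriang.R	attention
ORBinf.L	default-mode
ORBinf.R	default-mode
ROL.L	sensory-motor
ROL.R	sensory-motor
SMA.L	sensory-motor
SMA.R	sensory-motor
OLF.L	subcortical
OLF.R	subcortical
SFGmed.L	default-mode
SFGmed.R	default-mode
ORBsupmed.L	default-mode
ORBsupmed.R	default-mode
REC.L	default-mode
REC.R	default-mode
INS.L	subcortical
INS.R	subcortical
ACG.L	default-mode
ACG.R	default-mode
DCG.L	default-mode
DCG.R	default-mode
PCG.L	default-mode
PCG.R	default-mode
HIP.L	default-mode
HIP.R	default-mode
PHG.L	default-mode
PHG.R	default-mode
AMYG.L	subcortical
AMYG.R	subcortical
CAL.L	visual
CAL.R	visual
CUN.L	visual
CUN.R	visual
LING.L	visual
LING.R	visual
SOG.L	visual
SOG.R	visual
MOG.L	visual
MOG.R	visual
IOG.L	visual
IOG.R	visual
FFG.L	visual
FFG.R	visual
PoCG.L	sensory-motor
PoCG.R	sensory-motor
SPG.L	attention
SPG.R	attention
IPL.L	attention
IPL.R	attention
SMG.L	attention
SMG.R	attention
ANG.L	default-mode
ANG.R	default-mode
PCUN.L	default-mode
PCUN.R	default-mode
PCL.L	sensory-motor
PCL.R	sensory-motor
CAU.L	subcortical
CAU.R	subcortical
PUT.L	subcortical
PUT.R	subcortical
PAL.L	subcortical
PAL.R	subcortical
THA.L	subcortical
THA.R	subcortical
HES.L	auditory
HES.R	auditory
STG.L	auditory
STG.R	auditory
TPOsup.L	auditory
TPOsup.R	auditory
MTG.L	default-mode
MTG.R	default-mode
TPOmid.L	default-mode
TPOmid.R	default-mode
ITG.L	default-mode
ITG.R	default-mode
Crus1.L	cerebellum
Crus1.R	cerebellum
Crus2.L	cerebellum
Crus2.R	cerebellum
C3.L	cerebellum
C3.R	cerebellum
C45.L	cerebellum
C45.R	cerebellum
C6.L	cerebellum
C6.R	cerebellum
C7b.L	cerebellum
C7b.R	cerebellum
C8.L	cerebellum
C8.R	cerebellum
C9.L	cerebellum
C9.R	cerebellum
C10.L	cerebellum
C10.R	cerebellum
Vermis12	cerebellum
Vermis3	cerebellum
Vermis45	cerebellum
Vermis6	cerebellum
Vermis7	cerebellum
Vermis8	cerebellum
Vermis9	cerebellum
Vermis10	cerebellum
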