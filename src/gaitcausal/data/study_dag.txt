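# Structural causal model of net metabolic power during walking in
# ambulatory children with cerebral palsy (GMFCS I-III).
#
# BrainInjury is the early brain injury: a latent (unmeasured) common cause
# of the four neurological/physical impairments. Demographics (Age, Sex,
# Height, Mass) are potential confounders. Walking speed is affected by the
# impairments and demographics but itself affects only GDI and metabolic
# power. This reconstruction is one DAG consistent with the published
# adjustment sets and prose, not necessarily the authors' exact figure.

latent: BrainInjury

BrainInjury -> Spasticity
BrainInjury -> Strength
BrainInjury -> SMC
BrainInjury -> DMC

Sex -> Height
Sex -> Mass
Age -> Height
Age -> Mass
Height -> Mass

Age -> Spasticity
Age -> Strength
Age -> SMC
Age -> DMC
Height -> Spasticity
Height -> Strength
Height -> SMC
Height -> DMC
Mass -> Spasticity
Mass -> Strength
Mass -> SMC
Mass -> DMC

Spasticity -> Speed
Strength -> Speed
SMC -> Speed
DMC -> Speed
Age -> Speed
Height -> Speed
Mass -> Speed

Speed -> GDI
Spasticity -> GDI
Strength -> GDI
SMC -> GDI
DMC -> GDI
Age -> GDI
Height -> GDI
Mass -> GDI

GDI -> MetPower
Speed -> MetPower
Spasticity -> MetPower
Strength -> MetPower
SMC -> MetPower
DMC -> MetPower
Age -> MetPower
Height -> MetPower
Mass -> MetPower
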