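# Standard transformed Gibbs energies of reaction (kJ/mol) for the default network.
# Conditions assumed: ionic strength 0.2 M, pMg 3, pH 6.8, 298.15 K.
# Values are estimates in the style of component-contribution predictions and are
# packaged as replaceable input data; sd records the estimate uncertainty (not used
# when computing feasible ranges, recorded for provenance). Sinks carry no entry.
reaction,dG0,sd,source
ERG10,26.1,1.5,estimate
ERG13,-23.7,2.0,estimate
HMG1,-38.5,3.0,estimate
HMG2,-38.5,3.0,estimate
ERG12,-16.4,2.0,estimate
ERG8,-13.0,2.0,estimate
MVD1,-27.0,3.0,estimate
IDI1,0.9,1.0,estimate
ERG20a,-37.8,3.0,estimate
ERG20b,-36.5,3.0,estimate
BTS1,-35.9,3.0,estimate
CrtE,-35.9,3.0,estimate
ERG9a,-22.0,3.0,estimate
ERG9b,-48.0,4.0,estimate
CrtYBa,-46.1,4.0,estimate
CrtI1,-41.0,4.0,estimate
CrtI2,-41.0,4.0,estimate
CrtI3,-41.0,4.0,estimate
CrtI4,-41.0,4.0,estimate
CrtYBb,-26.6,3.0,estimate
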