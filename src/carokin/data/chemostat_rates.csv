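# Measured chemostat growth and carotenoid production rates for the three
# recombinant beta-carotene strains at two dilution rates (in-package fixture).
# Rates in nmol/gDCW/h; D in 1/h; *_lo/*_hi are 95% confidence bounds.
strain,D,D_lo,D_hi,lyc_rate,lyc_lo,lyc_hi,bcar_rate,bcar_lo,bcar_hi
b_car2,0.101,0.0971,0.1048,94.4,85.4,104.4,151.3,140.3,163.4
b_car2,0.254,0.2507,0.2580,84.3,74.1,94.9,184.2,138.8,230.5
b_car3,0.101,0.0971,0.1048,472.0,430.7,518.5,227.1,207.6,240.9
b_car3,0.254,0.2507,0.2580,126.5,123.2,129.9,294.8,198.6,391.4
b_car4,0.101,0.0971,0.1048,760.7,647.5,877.1,185.3,166.4,201.8
b_car4,0.254,0.2507,0.2580,392.9,352.6,434.6,453.6,361.2,547.4
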