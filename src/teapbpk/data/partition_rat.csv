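# Rat tissue:blood partition coefficients (dimensionless). EGC was not
# modelled in rats; rest_of_body is fixed at 1.00 by convention.
compartment,EGCg,ECg,EC
adipose,0.20,0.75,0.08
bone,1.62,4.00,0.39
brain,3.15,7.84,0.73
gut,2.04,4.82,0.63
heart,1.27,2.65,0.62
kidney,1.43,3.10,0.63
liver,1.50,3.37,0.59
lung,1.70,3.83,0.65
muscle,1.02,1.97,0.59
skin,1.79,4.23,0.55
spleen,0.98,1.85,0.63
rest_of_body,1.00,1.00,1.00
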