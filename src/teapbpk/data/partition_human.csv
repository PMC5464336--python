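# Human tissue:blood partition coefficients (dimensionless). ECg was not
# modelled in humans; rest_of_body is fixed at 1.00 by convention.
compartment,EGCg,EGC,EC
adipose,0.15,0.01,0.01
bone,3.22,0.48,0.41
brain,3.12,0.69,0.62
gut,2.49,0.53,0.55
heart,1.00,0.51,0.50
kidney,1.38,0.56,0.53
liver,2.05,0.59,0.55
lung,0.57,0.51,0.51
muscle,1.38,0.54,0.52
skin,1.60,0.53,0.50
spleen,1.40,0.56,0.54
rest_of_body,1.00,1.00,1.00
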