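# Human tissue blood flows (% of cardiac output) and volumes (% of body
# weight). Same conventions as the rat table; liver flow is total hepatic.
compartment,flow_pct_co,volume_pct_bw
adipose,5.00,12.00
blood,,7.71
bone,5.00,8.56
brain,12.00,0.02
gut,17.00,1.71
heart,4.00,0.47
kidney,19.00,0.44
liver,25.00,2.57
lung,,0.76
muscle,17.00,40.00
skin,5.00,3.71
spleen,2.00,0.26
rest_of_body,8.00,21.60
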