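# Rat tissue blood flows (% of cardiac output) and volumes (% of body
# weight). Blood and lung carry no perfusion entry (lung sees total venous
# return). The liver flow is TOTAL hepatic flow (arterial + portal).
compartment,flow_pct_co,volume_pct_bw
adipose,7.00,7.60
blood,,8.16
bone,12.20,4.15
brain,2.00,0.57
gut,13.10,2.70
heart,4.90,0.33
kidney,14.10,0.73
liver,17.50,3.66
lung,,0.50
muscle,27.80,40.40
skin,5.80,19.00
spleen,2.00,0.20
rest_of_body,8.70,12.00
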