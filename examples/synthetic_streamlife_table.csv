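stream,width_m,depth_cm,mech,mean_days,n_dead
alder,3.2,6.0,senescence,6.3,18
alder,3.2,6.0,predation,4.1,55
alder,3.2,6.0,stranding,4.6,9
birch,3.9,9.1,senescence,7.5,25
birch,3.9,9.1,predation,5.2,48
birch,3.9,9.1,stranding,5.4,7
cedar,4.5,13.0,senescence,8.8,30
cedar,4.5,13.0,predation,6.2,42
cedar,4.5,13.0,stranding,6.5,8
dogwood,5.8,17.0,senescence,10.1,38
dogwood,5.8,17.0,predation,7.0,34
dogwood,5.8,17.0,stranding,7.2,6
elder,7.0,21.0,senescence,11.0,41
elder,7.0,21.0,predation,8.0,30
elder,7.0,21.0,stranding,8.4,5
fir,8.4,25.0,senescence,12.2,45
fir,8.4,25.0,predation,9.0,26
fir,8.4,25.0,stranding,9.3,4
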