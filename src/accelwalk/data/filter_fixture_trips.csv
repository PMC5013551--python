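vehicle_id,t_start,duration_h,mean_speed_kmh,path_length_km
A,2011-05-01T08:00:00,0.16666666666666666,5.4,0.9
B,2011-05-01T08:00:00,0.06666666666666667,22.5,1.5
C,2011-05-01T08:00:00,0.25,20.0,5.0
D,2011-05-01T08:00:00,0.16666666666666666,6.0,1.0
E,2011-05-01T08:00:00,0.08333333333333333,24.0,2.0
F,2011-05-01T08:00:00,0.5,24.0,12.0
G,2011-05-01T08:00:00,0.13333333333333333,24.75,3.3
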