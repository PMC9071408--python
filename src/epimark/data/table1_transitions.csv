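compound,precursor_mz,product_mz,fragmentor,collision_energy,cell_accel,ret_time,ret_window,polarity
Am,282,136.0,92,13,2,16.4,5,Positive
Am 13C,293,141.0,92,13,2,16.4,5,Positive
Cm,258,112.1,60,9,2,10.0,5,Positive
Cm 13C,268,116.1,60,9,2,10.0,5,Positive
D,247,115.0,80,10,2,3.9,5,Positive
D 13C,255,119.0,80,10,2,3.9,5,Positive
Gm,298,152.0,72,5,2,13.2,5,Positive
Gm 13C,309,157.0,72,5,2,13.2,5,Positive
I,269,137.0,76,5,2,10.5,5,Positive
I 13C,279,142.0,76,5,2,10.5,5,Positive
i6A,336,204.0,80,15,2,22.3,5,Positive
i6A 13C,351,214.0,80,15,2,22.3,5,Positive
m1A,282,150.0,92,17,2,5.6,6,Positive
m1A C13,293,156.0,92,17,2,5.6,6,Positive
m1G,298,166.0,82,9,2,13.0,5,Positive
m1G C13,309,172.0,82,9,2,13.0,5,Positive
"m2,2G",312,180.0,82,9,2,15.4,5,Positive
"m2,2G 13C",324,187.0,82,9,2,15.4,5,Positive
"m6,6A",296,164.1,102,17,2,18.9,5,Positive
"m6,6A 13C",308,171.0,102,17,2,18.9,5,Positive
m2A,282,150.1,92,17,2,16.9,5,Positive
m2A 13C,293,156.0,92,17,2,16.9,5,Positive
m2G,298,166.1,82,9,2,13.6,5,Positive
m2G 13C,309,172.0,82,9,2,13.6,5,Positive
m3C,258,126.0,40,9,2,6.8,6,Positive
m3C C13,268,131.0,40,9,2,6.8,6,Positive
m3U,259,127.0,76,5,2,12.6,6,Positive
m3U 13C,269,132.0,76,5,2,12.6,6,Positive
m5C,258,126.1,40,9,2,9.5,5,Positive
m5C 13C,268,131.0,40,9,2,9.5,5,Positive
m5U,259,127.0,76,5,2,11.2,6,Positive
m5U 13C,269,132.0,76,5,2,11.2,6,Positive
m6A,282,150.1,92,17,2,17.1,5,Positive
m6A 13C,293,156.0,92,17,2,17.1,5,Positive
m7G,298,166.1,82,9,2,9.7,6,Positive
m7G C13,309,172.0,82,9,2,9.7,6,Positive
mcm5U,317,185.0,66,5,2,13.2,5,Positive
mcm5U 13C,329,192.0,66,5,2,13.2,5,Positive
ms2i6A,382,250.0,80,15,2,22.4,5,Positive
ms2i6A 13C,398,261.0,80,15,2,22.4,5,Positive
Psi,245,209.0,81,5,2,4.2,5,Positive
Psi C13,254,218.0,81,5,2,4.2,5,Positive
Q,410,163.0,80,15,2,11.6,6,Positive
Q 13C,427,170.0,80,15,2,11.6,6,Positive
s2C,260,128.0,40,10,2,9.2,6,Positive
s2C 13C,269,132.0,40,10,2,9.2,6,Positive
s2U,261,129.0,66,5,2,11.1,6,Positive
s2U 13C,270,133.0,66,5,2,11.1,6,Positive
t6A,413,281.0,80,15,2,15.2,8,Positive
t6A 13C,428,291.0,80,15,2,15.2,8,Positive
Tm,273,127.0,66,5,2,14.9,5,Positive
Tm 13C,286,134.0,66,5,2,14.9,5,Positive
Um,259,113.0,66,5,2,12.1,5,Positive
Um 13C,269,117.0,66,5,2,12.1,5,Positive
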