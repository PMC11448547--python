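trajectory_id,year,count
t1,2025,250.0
t1,2030,380.0
t1,2035,560.0
t1,2040,850.0
t1,2045,1300.0
t1,2050,1900.0
t1,2055,2900.0
t1,2060,4400.0
t1,2065,6600.0
t1,2070,9900.0
t1,2075,15000.0
t1,2080,22000.0
t2,2025,280.0
t2,2030,420.0
t2,2035,630.0
t2,2040,950.0
t2,2045,1400.0
t2,2050,2100.0
t2,2055,3200.0
t2,2060,4800.0
t2,2065,7200.0
t2,2070,10800.0
t2,2075,16200.0
t2,2080,24300.0
t3,2025,310.0
t3,2030,470.0
t3,2035,700.0
t3,2040,1050.0
t3,2045,1600.0
t3,2050,2400.0
t3,2055,3600.0
t3,2060,5400.0
t3,2065,8100.0
t3,2070,12200.0
t3,2075,18300.0
t3,2080,27400.0
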