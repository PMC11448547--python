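id,country,sex,birth_date,death_date,death_year_only
r1,US,F,1889-01-15,2000-06-30,
r2,US,M,1888-03-01,2001-01-10,
r3,US,F,1895-10-01,2006-11-20,
r4,US,F,1897-05-05,2008-02-01,
r5,US,,1892-07-20,,2003
r6,JP,F,1893-02-10,2005-06-15,
r7,JP,F,1896-08-01,2007-03-10,
r8,JP,M,1898-11-11,2009-04-05,
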