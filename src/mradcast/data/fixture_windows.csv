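country,window_start,window_end
JP,2005.0,
US,2000.0,2010.0
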