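panel_id,repetition,category,event_type,time_s,attribute
P01,1,primary-sensory,press,0.0,sweet
P01,1,primary-sensory,stop,30.0,
P02,1,primary-sensory,press,15.0,sour
P02,1,primary-sensory,stop,30.0,
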