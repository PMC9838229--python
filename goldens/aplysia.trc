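1	phase	pretrain
1	stimulus	cs
1	fire	s_cs cs
3	phase	train
3	stimulus	cs
3	fire	s_cs cs
3	stimulus	us
3	fire	s_us us
3	deliver	s_us->motor us
3	fire	motor motor(us)
3	action	motor(us)
3	weight	w(s_cs->motor)=1
4	deliver	s_cs->motor cs
4	fire	motor motor(cs)
4	action	motor(cs)
5	stimulus	cs
5	fire	s_cs cs
5	stimulus	us
5	fire	s_us us
5	deliver	s_cs->motor cs
5	deliver	s_us->motor us
5	fire	motor motor(cs)
5	action	motor(cs)
5	fire	motor motor(us)
5	action	motor(us)
5	weight	w(s_cs->motor)=2
8	phase	posttrain
8	stimulus	cs
8	fire	s_cs cs
8	deliver	s_cs->motor cs
8	fire	motor motor(cs)
8	action	motor(cs)
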