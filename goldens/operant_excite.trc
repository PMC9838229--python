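1	phase	learn
1	stimulus	watch(i1)
1	fire	s_watch watch(i1)
1	stimulus	excite
1	fire	s_excite excite
1	deliver	s_watch->spot watch(i1)
1	fire	spot spot(i1)
1	weight	w(s_watch->accept)=1
1	weight	w(s_watch->spot)=0
2	deliver	s_watch->accept watch(i1)
2	fire	accept accept(i1)
2	action	accept(i1)
3	phase	repeat
3	stimulus	watch(i1)
3	fire	s_watch watch(i1)
3	deliver	s_watch->accept watch(i1)
3	fire	accept accept(i1)
3	action	accept(i1)
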