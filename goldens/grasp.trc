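1	phase	reach
1	stimulus	view(obj(toy,3))
1	fire	s_obj view(obj(toy,3))
1	stimulus	view(hand(3))
1	fire	s_hand view(hand(3))
1	deliver	s_hand->grasp view(hand(3))
1	stp	s_obj->grasp open d=1
1	deliver	s_obj->grasp view(obj(toy,3))
1	fire	grasp grasp(obj(toy,3))
1	action	grasp(obj(toy,3))
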