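1	phase	tracking
1	stimulus	move(obj(toy,1))
1	fire	s_move move(obj(toy,1))
1	deliver	s_move->focus move(obj(toy,1))
1	fire	focus focus(obj(toy,2))
2	stimulus	move(obj(toy,2))
2	fire	s_move move(obj(toy,2))
2	stimulus	see(obj(toy,2))
2	fire	s_see see(obj(toy,2))
2	deliver	s_move->focus move(obj(toy,2))
2	deliver	s_see->assim see(obj(toy,2))
2	deliver	s_see->look see(obj(toy,2))
2	fire	focus focus(obj(toy,3))
2	fire	assim track(obj(toy,2))
3	stimulus	halt(obj(toy,3))
3	fire	s_halt halt(obj(toy,3))
3	deliver	s_halt->grasp halt(obj(toy,3))
3	fire	grasp grasp(obj(toy,3))
3	action	grasp(obj(toy,3))
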