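1	phase	hide_at_a
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
3	stimulus	see(obj(s1,3))
3	fire	s_see see(obj(s1,3))
3	stimulus	stop(obj(toy,3))
3	fire	s_stop stop(obj(toy,3))
3	deliver	s_see->assim see(obj(s1,3))
3	deliver	s_see->look see(obj(s1,3))
3	fire	look look(obj(s1,3))
3	action	look(obj(s1,3))
3	weight	w(look->search)=1
4	deliver	look->search look(obj(s1,3))
4	fire	search search(obj(s1,3))
4	action	search(obj(s1,3))
4	stp	s_view->grasp open d=2
5	stimulus	view(obj(toy,3))
5	fire	s_view view(obj(toy,3))
5	deliver	s_view->grasp view(obj(toy,3))
5	fire	grasp grasp(obj(toy,3))
5	action	grasp(obj(toy,3))
7	phase	hide_at_b
7	stimulus	move(obj(toy,5))
7	fire	s_move move(obj(toy,5))
7	deliver	s_move->focus move(obj(toy,5))
7	fire	focus focus(obj(toy,6))
8	stimulus	move(obj(toy,6))
8	fire	s_move move(obj(toy,6))
8	stimulus	see(obj(toy,6))
8	fire	s_see see(obj(toy,6))
8	deliver	s_move->focus move(obj(toy,6))
8	deliver	s_see->assim see(obj(toy,6))
8	deliver	s_see->look see(obj(toy,6))
8	fire	focus focus(obj(toy,7))
8	fire	assim track(obj(toy,6))
9	stimulus	see(obj(s2,7))
9	fire	s_see see(obj(s2,7))
9	stimulus	stop(obj(toy,7))
9	fire	s_stop stop(obj(toy,7))
9	deliver	s_see->assim see(obj(s2,7))
9	deliver	s_see->look see(obj(s2,7))
9	fire	look look(obj(s2,7))
9	action	look(obj(s2,7))
9	deliver	look->search look(obj(s2,7))
9	fire	search search(obj(s2,7))
9	action	search(obj(s2,7))
9	stp	s_view->grasp open d=2
9	weight	w(look->search)=2
10	stimulus	view(obj(toy,7))
10	fire	s_view view(obj(toy,7))
10	deliver	s_view->grasp view(obj(toy,7))
10	fire	grasp grasp(obj(toy,7))
10	action	grasp(obj(toy,7))
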