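1	phase	phase_I_trial1
1	stimulus	view(box(f,toy,2))
1	fire	s_boxview view(box(f,toy,2))
1	stm	push <inboxmem> view(box(f,toy,2))
2	stimulus	move(obj(f,3))
2	fire	s_move move(obj(f,3))
2	deliver	s_move->focus move(obj(f,3))
2	fire	focus focus(obj(f,4))
3	stimulus	see(obj(s1,4))
3	fire	s_see see(obj(s1,4))
3	deliver	s_see->assim see(obj(s1,4))
3	deliver	s_see->look see(obj(s1,4))
3	fire	look look(obj(s1,4))
3	action	look(obj(s1,4))
3	stm	push <lookmem> look(obj(s1,4))
4	stimulus	view(obj(f,5))
4	fire	s_view view(obj(f,5))
4	deliver	s_view->openbox view(obj(f,5))
4	stm	pop <inboxmem> view(box(f,toy,2))
4	fire	openbox open(box(f,5))
4	action	open(box(f,5))
5	stimulus	spot(box(f,empty,5))
5	fire	s_spot spot(box(f,empty,5))
5	deliver	s_spot->spotneg spot(box(f,empty,5))
5	deliver	s_spot->grasp spot(box(f,empty,5))
5	fire	spotneg spotneg(box(f,5))
5	weight	w(s_halt->search)=1
8	phase	phase_I_trial2
8	stimulus	view(box(f,toy,2))
8	fire	s_boxview view(box(f,toy,2))
8	stm	push <inboxmem> view(box(f,toy,2))
9	stimulus	move(obj(f,3))
9	fire	s_move move(obj(f,3))
9	deliver	s_move->focus move(obj(f,3))
9	fire	focus focus(obj(f,4))
10	stimulus	see(obj(s1,4))
10	fire	s_see see(obj(s1,4))
10	deliver	s_see->assim see(obj(s1,4))
10	deliver	s_see->look see(obj(s1,4))
10	fire	look look(obj(s1,4))
10	action	look(obj(s1,4))
10	stm	push <lookmem> look(obj(s1,4))
11	stimulus	view(obj(f,5))
11	fire	s_view view(obj(f,5))
11	deliver	s_view->openbox view(obj(f,5))
11	stm	pop <inboxmem> view(box(f,toy,2))
11	fire	openbox open(box(f,5))
11	action	open(box(f,5))
12	stimulus	spot(box(f,empty,5))
12	fire	s_spot spot(box(f,empty,5))
12	deliver	s_spot->spotneg spot(box(f,empty,5))
12	deliver	s_spot->grasp spot(box(f,empty,5))
12	fire	spotneg spotneg(box(f,5))
12	weight	w(s_halt->search)=2
15	phase	phase_II
15	stimulus	view(box(f,toy,2))
15	fire	s_boxview view(box(f,toy,2))
15	stm	push <inboxmem> view(box(f,toy,2))
16	stimulus	move(obj(f,3))
16	fire	s_move move(obj(f,3))
16	deliver	s_move->focus move(obj(f,3))
16	fire	focus focus(obj(f,4))
17	stimulus	see(obj(s1,4))
17	fire	s_see see(obj(s1,4))
17	deliver	s_see->assim see(obj(s1,4))
17	deliver	s_see->look see(obj(s1,4))
17	fire	look look(obj(s1,4))
17	action	look(obj(s1,4))
17	stm	push <lookmem> look(obj(s1,4))
18	stimulus	halt(obj(s1,4))
18	fire	s_halt halt(obj(s1,4))
18	deliver	s_halt->grasp halt(obj(s1,4))
18	deliver	s_halt->search halt(obj(s1,4))
18	stm	pop <lookmem> look(obj(s1,4))
18	fire	search search(obj(s1,4))
18	action	search(obj(s1,4))
18	stp	s_view->grasp open d=2
19	stimulus	view(obj(toy,4))
19	fire	s_view view(obj(toy,4))
19	deliver	s_view->grasp view(obj(toy,4))
19	deliver	s_view->openbox view(obj(toy,4))
19	fire	grasp grasp(obj(toy,4))
19	action	grasp(obj(toy,4))
23	phase	phase_III
23	stimulus	view(box(f,toy,2))
23	fire	s_boxview view(box(f,toy,2))
23	stm	push <inboxmem> view(box(f,toy,2))
24	stimulus	move(obj(f,3))
24	fire	s_move move(obj(f,3))
24	deliver	s_move->focus move(obj(f,3))
24	fire	focus focus(obj(f,4))
25	stimulus	see(obj(s1,4))
25	fire	s_see see(obj(s1,4))
25	deliver	s_see->assim see(obj(s1,4))
25	deliver	s_see->look see(obj(s1,4))
25	fire	look look(obj(s1,4))
25	action	look(obj(s1,4))
25	stm	push <lookmem> look(obj(s1,4))
26	stimulus	view(obj(f,5))
26	fire	s_view view(obj(f,5))
26	deliver	s_view->openbox view(obj(f,5))
26	stm	pop <inboxmem> view(box(f,toy,2))
26	fire	openbox open(box(f,5))
26	action	open(box(f,5))
27	stimulus	spot(box(f,empty,5))
27	fire	s_spot spot(box(f,empty,5))
27	deliver	s_spot->spotneg spot(box(f,empty,5))
27	deliver	s_spot->grasp spot(box(f,empty,5))
27	fire	spotneg spotneg(box(f,5))
27	weight	w(s_halt->search)=3
29	stimulus	halt(obj(s1,4))
29	fire	s_halt halt(obj(s1,4))
29	deliver	s_halt->grasp halt(obj(s1,4))
29	deliver	s_halt->search halt(obj(s1,4))
29	stm	pop <lookmem> look(obj(s1,4))
29	fire	search search(obj(s1,4))
29	action	search(obj(s1,4))
29	stp	s_view->grasp open d=2
30	stimulus	view(obj(toy,4))
30	fire	s_view view(obj(toy,4))
30	deliver	s_view->grasp view(obj(toy,4))
30	deliver	s_view->openbox view(obj(toy,4))
30	fire	grasp grasp(obj(toy,4))
30	action	grasp(obj(toy,4))
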