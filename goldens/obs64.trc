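1	phase	phase_Ia
1	stimulus	open(box(f,toy,2))
1	fire	s_open open(box(f,toy,2))
1	stimulus	close(box(f,covered,2))
1	fire	s_close close(box(f,covered,2))
1	deliver	s_open->image open(box(f,toy,2))
1	deliver	s_close->image close(box(f,covered,2))
1	fire	image image(box(f,toy,2))
1	store	{image(box(f,toy,2))}
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
4	recall	{image(box(f,toy,2))} -> s_view->openbox
4	fire	openbox open(box(f,5))
4	action	open(box(f,5))
4	weight	w(s_view->openbox)=2
5	stimulus	spot(box(f,empty,5))
5	fire	s_spot spot(box(f,empty,5))
5	deliver	s_spot->spotneg spot(box(f,empty,5))
5	deliver	s_spot->grasp spot(box(f,empty,5))
5	fire	spotneg spotneg(box(f,5))
5	weight	w(s_halt->search)=1
5	block	s_view->openbox
6	stimulus	halt(obj(s1,4))
6	fire	s_halt halt(obj(s1,4))
6	deliver	s_halt->grasp halt(obj(s1,4))
6	deliver	s_halt->viewmem halt(obj(s1,4))
6	fire	viewmem evoke(obj(s1,4))
6	stm	pop <lookmem> look(obj(s1,4))
6	recall	{image(box(f,toy,2))} -> viewmem->search
6	fire	search search(obj(s1,4))
6	action	search(obj(s1,4))
6	stp	s_view->grasp open d=2
6	weight	w(viewmem->search)=1
7	stimulus	view(obj(toy,4))
7	fire	s_view view(obj(toy,4))
7	deliver	s_view->grasp view(obj(toy,4))
7	fire	grasp grasp(obj(toy,4))
7	action	grasp(obj(toy,4))
12	phase	phase_Ib
12	stimulus	open(box(f,toy,2))
12	fire	s_open open(box(f,toy,2))
12	stimulus	close(box(f,covered,2))
12	fire	s_close close(box(f,covered,2))
12	deliver	s_open->image open(box(f,toy,2))
12	deliver	s_close->image close(box(f,covered,2))
12	fire	image image(box(f,toy,2))
12	store	{image(box(f,toy,2))}
13	stimulus	move(obj(f,7))
13	fire	s_move move(obj(f,7))
13	deliver	s_move->focus move(obj(f,7))
13	fire	focus focus(obj(f,8))
14	stimulus	see(obj(s2,8))
14	fire	s_see see(obj(s2,8))
14	deliver	s_see->assim see(obj(s2,8))
14	deliver	s_see->look see(obj(s2,8))
14	fire	look look(obj(s2,8))
14	action	look(obj(s2,8))
14	stm	push <lookmem> look(obj(s2,8))
15	stimulus	view(obj(f,9))
15	fire	s_view view(obj(f,9))
17	stimulus	halt(obj(s2,8))
17	fire	s_halt halt(obj(s2,8))
17	deliver	s_halt->grasp halt(obj(s2,8))
17	deliver	s_halt->viewmem halt(obj(s2,8))
17	fire	viewmem evoke(obj(s2,8))
17	stm	pop <lookmem> look(obj(s2,8))
17	recall	{image(box(f,toy,2))} -> viewmem->search
17	fire	search search(obj(s2,8))
17	action	search(obj(s2,8))
17	stp	s_view->grasp open d=2
17	weight	w(viewmem->search)=2
18	stimulus	view(obj(toy,8))
18	fire	s_view view(obj(toy,8))
18	deliver	s_view->grasp view(obj(toy,8))
18	fire	grasp grasp(obj(toy,8))
18	action	grasp(obj(toy,8))
23	phase	phase_II
23	stimulus	open(box(f,toy,2))
23	fire	s_open open(box(f,toy,2))
23	stimulus	close(box(f,covered,2))
23	fire	s_close close(box(f,covered,2))
23	deliver	s_open->image open(box(f,toy,2))
23	deliver	s_close->image close(box(f,covered,2))
23	fire	image image(box(f,toy,2))
23	store	{image(box(f,toy,2))}
24	stimulus	move(obj(f,11))
24	fire	s_move move(obj(f,11))
24	deliver	s_move->focus move(obj(f,11))
24	fire	focus focus(obj(f,12))
25	stimulus	see(obj(s3,12))
25	fire	s_see see(obj(s3,12))
25	deliver	s_see->assim see(obj(s3,12))
25	deliver	s_see->look see(obj(s3,12))
25	fire	look look(obj(s3,12))
25	action	look(obj(s3,12))
25	stm	push <lookmem> look(obj(s3,12))
26	stimulus	move(obj(f,13))
26	fire	s_move move(obj(f,13))
26	deliver	s_move->focus move(obj(f,13))
26	fire	focus focus(obj(f,14))
27	stimulus	see(obj(s4,14))
27	fire	s_see see(obj(s4,14))
27	deliver	s_see->assim see(obj(s4,14))
27	deliver	s_see->look see(obj(s4,14))
27	fire	look look(obj(s4,14))
27	action	look(obj(s4,14))
27	stm	push <lookmem> look(obj(s4,14))
28	stimulus	halt(obj(s4,14))
28	fire	s_halt halt(obj(s4,14))
28	deliver	s_halt->grasp halt(obj(s4,14))
28	deliver	s_halt->viewmem halt(obj(s4,14))
28	fire	viewmem evoke(obj(s4,14))
28	stm	pop <lookmem> look(obj(s3,12))
28	recall	{image(box(f,toy,2))} -> viewmem->search
28	fire	search search(obj(s3,12))
28	action	search(obj(s3,12))
28	stp	s_view->grasp open d=2
28	weight	w(viewmem->search)=3
29	stimulus	fail(obj(s3,12))
29	fire	s_fail fail(obj(s3,12))
29	deliver	s_fail->viewmem fail(obj(s3,12))
29	fire	viewmem evoke(obj(s3,12))
29	stm	pop <lookmem> look(obj(s4,14))
29	recall	{image(box(f,toy,2))} -> viewmem->search
29	fire	search search(obj(s4,14))
29	action	search(obj(s4,14))
29	stp	s_view->grasp open d=2
29	weight	w(viewmem->search)=4
30	stimulus	view(obj(toy,14))
30	fire	s_view view(obj(toy,14))
30	deliver	s_view->grasp view(obj(toy,14))
30	fire	grasp grasp(obj(toy,14))
30	action	grasp(obj(toy,14))
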