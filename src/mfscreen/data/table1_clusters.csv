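patient,view,side,total,n_clusters,sizes
1,CC,CB,10,3,5 4 1
1,CC,CUB,11,4,7 2 1 1
1,MLO,CB,8,6,3 1 1 1 1 1
1,MLO,CUB,12,3,8 2 2
2,CC,CB,7,2,6 1
2,CC,CUB,2,2,1 1
2,MLO,CB,9,1,9
2,MLO,CUB,4,2,2 2
3,CC,CB,13,3,11 1 1
3,CC,CUB,24,2,23 1
3,MLO,CB,15,4,9 2 2 2
3,MLO,CUB,12,9,2 2 2 1 1 1 1 1 1
4,CC,CB,14,5,5 4 2 2 1
4,CC,CUB,12,2,9 3
4,MLO,CB,15,3,12 2 1
4,MLO,CUB,10,5,5 2 1 1 1
5,CC,CB,8,5,3 2 1 1 1
5,CC,CUB,10,5,4 2 2 1 1
5,MLO,CB,19,4,11 6 1 1
5,MLO,CUB,2,2,1 1
6,CC,CB,24,5,18 3 1 1 1
6,CC,CUB,0,0,
6,MLO,CB,19,3,17 1 1
6,MLO,CUB,0,0,
7,CC,CB,12,4,9 1 1 1
7,CC,CUB,13,2,10 3
7,MLO,CB,15,4,11 2 1 1
7,MLO,CUB,11,5,3 3 3 1 1
8,CC,CB,19,7,6 4 3 2 2 1 1
8,CC,CUB,11,3,8 2 1
8,MLO,CB,17,3,14 2 1
8,MLO,CUB,8,6,2 2 1 1 1 1
9,CC,CB,12,7,5 2 1 1 1 1 1
9,CC,CUB,10,3,6 3 1
9,MLO,CB,12,2,10 2
9,MLO,CUB,9,6,3 2 1 1 1 1
11,CC,CB,9,3,6 2 1
11,CC,CUB,3,2,2 1
11,MLO,CB,9,6,3 2 1 1 1 1
11,MLO,CUB,1,1,1
12,CC,CB,15,4,12 1 1 1
12,CC,CUB,3,3,1 1 1
12,MLO,CB,15,6,6 4 2 1 1 1
12,MLO,CUB,4,4,1 1 1 1
13,CC,CB,23,3,19 2 2
13,CC,CUB,1,1,1
13,MLO,CB,28,3,26 1 1
13,MLO,CUB,7,4,3 2 1 1
14,CC,CB,4,2,3 1
14,CC,CUB,1,1,1
14,MLO,CB,6,3,2 2 2
14,MLO,CUB,4,1,4
16,CC,CB,10,4,6 2 1 1
16,CC,CUB,3,1,3
16,MLO,CB,17,3,15 1 1
16,MLO,CUB,6,2,4 2
17,CC,CB,9,4,6 1 1 1
17,CC,CUB,1,1,1
17,MLO,CB,14,2,13 1
17,MLO,CUB,6,2,5 1
18,CC,CB,14,8,5 3 1 1 1 1 1 1
18,CC,CUB,2,1,2
18,MLO,CB,18,5,8 6 2 1 1
18,MLO,CUB,2,2,1 1
19,CC,CB,10,1,10
19,CC,CUB,1,1,1
19,MLO,CB,6,1,6
19,MLO,CUB,0,0,
20,CC,CB,24,2,19 5
20,CC,CUB,8,3,6 1 1
20,MLO,CB,22,2,19 3
20,MLO,CUB,9,3,7 1 1
21,CC,CB,14,5,9 2 1 1 1
21,CC,CUB,5,4,2 1 1 1
21,MLO,CB,12,7,2 2 2 2 2 1 1
21,MLO,CUB,5,5,1 1 1 1 1
23,CC,CB,5,3,3 1 1
23,CC,CUB,9,2,8 1
23,MLO,CB,11,4,4 4 2 1
23,MLO,CUB,7,2,6 1
24,CC,CB,24,3,13 6 5
24,CC,CUB,7,4,3 2 1 1
24,MLO,CB,15,3,12 2 1
24,MLO,CUB,9,3,7 1 1
25,CC,CB,19,5,12 4 1 1 1
25,CC,CUB,5,4,2 1 1 1
25,MLO,CB,17,4,6 5 5 1
25,MLO,CUB,9,3,5 3 1
26,CC,CB,4,1,4
26,CC,CUB,7,4,3 2 1 1
26,MLO,CB,10,1,10
26,MLO,CUB,6,1,6
27,CC,CB,13,4,10 1 1 1
27,CC,CUB,1,1,1
27,MLO,CB,11,6,4 3 1 1 1 1
27,MLO,CUB,4,3,2 1 1
28,CC,CB,13,6,5 2 2 2 1 1
28,CC,CUB,4,3,2 1 1
28,MLO,CB,16,6,8 4 1 1 1 1
28,MLO,CUB,6,2,5 1
29,CC,CB,14,3,7 6 1
29,CC,CUB,9,4,5 2 1 1
29,MLO,CB,14,3,6 6 2
29,MLO,CUB,5,1,5
30,CC,CB,8,4,2 2 2 2
30,CC,CUB,12,6,3 3 2 2 1 1
30,MLO,CB,13,3,11 1 1
30,MLO,CUB,9,3,6 2 1
31,CC,CB,12,2,9 3
31,CC,CUB,3,2,2 1
31,MLO,CB,18,4,8 7 2 1
31,MLO,CUB,7,3,3 3 1
32,CC,CB,40,8,16 7 4 4 4 2 2 1
32,CC,CUB,30,13,6 5 3 3 3 2 2 1 1 1 1 1 1
32,MLO,CB,36,11,12 6 4 3 3 3 1 1 1 1 1
32,MLO,CUB,19,10,5 4 2 2 1 1 1 1 1 1
33,CC,CB,8,3,5 2 1
33,CC,CUB,4,4,1 1 1 1
33,MLO,CB,10,2,7 3
33,MLO,CUB,8,2,7 1
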