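# 16-node, 21-edge demonstration network (reconstructed by constraint search;
# see scripts/build_toy_fixture.py). Node 2's neighborhood, the hop-distance
# profile from node 2, and all 16 neighbor-degree entropies match the
# documented worked example.
1 2
2 3
2 4
2 5
3 7
3 15
5 6
5 7
5 13
6 7
6 8
6 9
8 9
8 10
8 11
9 11
9 14
10 11
10 12
11 12
15 16
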