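"""Random walk with restart on a toy interaction network.

Known disease genes seed the walk; candidate genes closer to the seeds in
the network accumulate more steady-state probability and rank higher.
"""

from generank import build_transition, make_network, rank_test_genes, rwr_steady_state

edges = [
    ("d1", "d2", 1.0), ("d1", "cand_near", 1.0), ("d2", "cand_near", 1.0),
    ("cand_near", "x1", 0.5), ("x1", "cand_far", 1.0), ("x1", "x2", 1.0),
    ("x2", "cand_isolated_side", 1.0),
]
net = make_network(edges, source_label="toy")
tm = build_transition(net)
p = rwr_steady_state(tm, sources={"d1", "d2"}, gamma=0.7)
rank_list = rank_test_genes(p, ["cand_near", "cand_far", "cand_isolated_side"], "toy")

for gene, rank in sorted(rank_list.ranks.items(), key=lambda it: it[1]):
    print(f"rank {rank}: {gene}  (steady-state probability {p[gene]:.4f})")
print("the candidate adjacent to both seeds outranks the distant ones")
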