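"""Discounted rating system, step by step, on the classic four-source case.

A candidate gene holds ranks 4, 2, 13 and 3 among 100 candidates in four
data sources.  Each source's ranks are binned into 5 equal-size rating
levels, each rating is discounted by log2(rank + 1), and the mean of the
discounted ratings is the combined score.
"""

from generank import RankList, assign_ratings, discounted_rating, drs_combine

genes = [f"c{i:03d}" for i in range(1, 101)]
lists = []
for label, target_rank in [("BP", 4), ("CC", 2), ("MF", 13), ("PPI", 3)]:
    order = list(genes)
    order.insert(target_rank - 1, "g8")
    lists.append(RankList(label, {g: r for r, g in enumerate(order[:100], 1)}))

for rl in lists:
    rating = assign_ratings(rl, 5)["g8"]
    dr = discounted_rating(rating, rl.ranks["g8"])
    print(f"{rl.source_label}: rank {rl.ranks['g8']:>2} -> rating {rating} "
          f"-> discounted rating {dr:.2f}")

result = drs_combine(lists, levels=5)
print(f"combined DRS score for g8: {result.scores['g8']:.2f} "
      f"(mean of the four discounted ratings; higher = stronger candidate)")
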