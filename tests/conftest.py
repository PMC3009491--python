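import numpy as np
import pytest

from generank import AnnotationTable, RankList


@pytest.fixture
def worked_example_lists():
    """Four sources of 100 candidates with gene g8 at ranks 4, 2, 13, 3.

    Mirrors the illustrated fusion walkthrough: each source ranks all 100
    candidates, and the gene of interest sits near the top everywhere.
    """
    genes = [f"c{i:03d}" for i in range(1, 101)]
    target = "g8"
    lists = []
    for label, target_rank in zip(("BP", "CC", "MF", "PPI"), (4, 2, 13, 3)):
        order = [g for g in genes]
        order.insert(target_rank - 1, target)
        ranks = {g: r for r, g in enumerate(order[:100], start=1)}
        assert ranks[target] == target_rank
        lists.append(RankList(source_label=label, ranks=ranks))
    return lists, target


@pytest.fixture
def small_table():
    return AnnotationTable(
        ontology_label="BP",
        entries={
            "g1": {"T1", "T2"},
            "g2": {"T1", "T2", "T3"},
            "g3": {"T3", "T4"},
            "g4": {"T5"},
        },
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20100118)
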