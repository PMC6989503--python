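import numpy as np
import pytest

import linklimit as ll


@pytest.fixture
def triangle():
    return ll.UndirectedGraph(3, {(0, 1), (1, 2), (0, 2)})


@pytest.fixture
def square_with_chord():
    # 4-cycle 0-1-2-3 plus the chord 0-2
    return ll.UndirectedGraph(4, {(0, 1), (1, 2), (2, 3), (0, 3), (0, 2)})


@pytest.fixture
def path4():
    return ll.UndirectedGraph(4, {(0, 1), (1, 2), (2, 3), (0, 2)})


@pytest.fixture
def er_small():
    return ll.er_graph(30, 70, seed=42)


@pytest.fixture
def chung_lu_small():
    deg = ll.powerlaw_degree_sequence(40, 6.0, seed=5)
    return ll.sample_from_q(ll.chung_lu_q_matrix(deg), seed=6)


def complete_graph(n):
    return ll.UndirectedGraph(n, {(i, j) for i in range(n) for j in range(i + 1, n)})


@pytest.fixture
def k4():
    return complete_graph(4)
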