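import random

import pytest

from consannot.hits import Hit


def make_hit(
    pid="P1",
    start=1,
    end=50,
    ev=1e-6,
    qid="q1",
    qlen=100,
    source="pfam",
    full=None,
):
    return Hit(
        query_id=qid,
        query_length=qlen,
        source=source,
        profile_id=pid,
        env_start=start,
        env_end=end,
        i_evalue=ev,
        full_evalue=full if full is not None else ev,
    )


def random_hits(rng: random.Random, n: int, qlen: int = 200, qid: str = "q1"):
    """Random hit set on one query; coordinates and e-values unconstrained."""
    hits = []
    for i in range(n):
        start = rng.randint(1, qlen - 10)
        end = rng.randint(start, min(qlen, start + rng.randint(5, 120)))
        ev = 10.0 ** rng.uniform(-30, -3.2)
        hits.append(make_hit(pid=f"P{i}", start=start, end=end, ev=ev,
                             qid=qid, qlen=qlen,
                             source=rng.choice(["pfam", "kofam", "tigrfam"])))
    return hits


@pytest.fixture
def greedy_instance():
    from consannot.synth import greedy_trap_instance

    return greedy_trap_instance()


@pytest.fixture
def fig7():
    from consannot.synth import fig7_instance

    return fig7_instance()
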