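import numpy as np
import pytest

from prophagekit import Match, PipelineConfig


def mk_match(
    query_start,
    query_end,
    target_start,
    target_end,
    strand="+",
    query_id="q",
    target_id="tg",
    query_length=12_000,
    evalue=0.0,
    score=100.0,
):
    return Match(
        query_id=query_id,
        target_id=target_id,
        query_start=query_start,
        query_end=query_end,
        target_start=target_start,
        target_end=target_end,
        strand=strand,
        evalue=evalue,
        score=score,
        query_length=query_length,
    )


def random_matches(rng: np.random.Generator, n: int) -> list:
    """Random small match instances for partition/monotonicity properties."""
    out = []
    for _ in range(n):
        qs = int(rng.integers(1, 900))
        span = int(rng.integers(10, 400))
        ts = int(rng.integers(1, 3000))
        out.append(
            mk_match(
                qs,
                min(1000, qs + span),
                ts,
                ts + span,
                strand="+" if rng.random() < 0.5 else "-",
                query_id="qA" if rng.random() < 0.7 else "qB",
                query_length=1000,
                evalue=0.0,
                score=float(span),
            )
        )
    return out


@pytest.fixture
def default_config():
    return PipelineConfig()
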