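import numpy as np
import pytest

from haplojigsaw import ChromSpan, Fragment


def make_fragment(start, end, fid=None, chrom="1", source="S0", side=0):
    return Fragment(
        id=fid or f"f{start}-{end}",
        chrom=chrom,
        start_bp=start,
        end_bp=end,
        source_sample=source,
        source_side=side,
        ancestry="NAT",
    )


def random_pool(rng, n_fragments, span_len=100, max_len=30, tie_prob=0.4):
    """Random fragment pool on span (1, span_len), with deliberate start ties."""
    frags = []
    starts = []
    for i in range(n_fragments):
        if starts and rng.random() < tie_prob:
            start = int(rng.choice(starts))
        else:
            start = int(rng.integers(1, span_len))
        starts.append(start)
        end = min(span_len, start + int(rng.integers(1, max_len)))
        frags.append(make_fragment(start, end, fid=f"f{i}", source=f"S{i % 7}"))
    return frags, ChromSpan("1", 1, span_len)


@pytest.fixture
def span100():
    return ChromSpan("1", 1, 100)


@pytest.fixture
def hand_pool():
    """The four-fragment pool whose greedy tiling is traced by hand:
    A(1,60), B(1,50), C(55,100), D(61,100) on span (1,100)."""
    return [
        make_fragment(1, 60, "A"),
        make_fragment(1, 50, "B"),
        make_fragment(55, 100, "C"),
        make_fragment(61, 100, "D"),
    ]
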