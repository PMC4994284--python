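import random

import pytest

from chromodraft.core import DIRECT, REVERSE, AlignmentRecord


def base_walk_interval(aln: AlignmentRecord, fragment_length: int) -> tuple[int, int]:
    """Brute-force oracle: walk the fragment base by base along the reference.

    Starting from the aligned block (whose per-base correspondence is fixed
    by the alignment coordinates and orientation), extend one base at a time
    toward both fragment ends and record every reference position the
    fragment would occupy.  Returns (min position, max position + 1).
    Independent of the closed-form placement equations.
    """
    pos: dict[int, int] = {}
    if aln.orientation == DIRECT:
        r = aln.ref_start
        for k in range(aln.fragment_start, aln.fragment_end):
            pos[k] = r
            r += 1
        r = aln.ref_start
        for k in range(aln.fragment_start - 1, -1, -1):
            r -= 1
            pos[k] = r
        r = aln.ref_end - 1
        for k in range(aln.fragment_end, fragment_length):
            r += 1
            pos[k] = r
    else:
        r = aln.ref_end - 1
        for k in range(aln.fragment_start, aln.fragment_end):
            pos[k] = r
            r -= 1
        r = aln.ref_end - 1
        for k in range(aln.fragment_start - 1, -1, -1):
            r += 1
            pos[k] = r
        r = aln.ref_start
        for k in range(aln.fragment_end, fragment_length):
            r -= 1
            pos[k] = r
    return min(pos.values()), max(pos.values()) + 1


def random_exact_alignment(
    rng: random.Random, max_len: int = 500
) -> tuple[AlignmentRecord, int]:
    """A random mismatch-free alignment plus its fragment length."""
    length = rng.randint(1, max_len)
    frag_start = rng.randint(0, length - 1)
    frag_end = rng.randint(frag_start + 1, length)
    block = frag_end - frag_start
    ref_start = rng.randint(0, 10_000)
    orientation = rng.choice((DIRECT, REVERSE))
    aln = AlignmentRecord(
        fragment_id="f",
        fragment_start=frag_start,
        fragment_end=frag_end,
        ref_id="chr1",
        ref_start=ref_start,
        ref_end=ref_start + block,
        orientation=orientation,
        score=2.0 * block,
    )
    return aln, length


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20_160_822)
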