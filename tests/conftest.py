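import numpy as np
import pytest

from paremodes.io_formats import HairpinRecord, Interval

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def make_perfect_stem(
    stem_len: int = 25, loop_len: int = 4, mir5p: tuple[int, int] = (2, 23), seed: int = 0
) -> HairpinRecord:
    """Perfect-complement stem hairpin with a recorded dot-bracket."""
    rng = np.random.default_rng(seed)
    stem5 = "".join(rng.choice(list("ACGU"), size=stem_len))
    loop = "A" * loop_len
    stem3 = "".join(_COMP[b] for b in reversed(stem5))
    seq = stem5 + loop + stem3
    structure = "(" * stem_len + "." * loop_len + ")" * stem_len
    return HairpinRecord(
        precursor_id="stem",
        sequence=seq,
        structure=structure,
        mir5p=Interval(*mir5p),
    )


@pytest.fixture
def perfect_stem() -> HairpinRecord:
    """25-bp stem, 4-nt loop, 54 nt total, miR-5p at [2, 23)."""
    return make_perfect_stem()
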