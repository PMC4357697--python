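import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from minicleave import DsSegment

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_segment(rng):
    """A 300-nt uniform-random duplex segment."""
    seq = "".join("ACGU"[i] for i in rng.integers(0, 4, size=300))
    return DsSegment(id="rand", top_sequence=seq)


def make_single_site_segment(length: int, i_top: int, seg_id: str = "sub") -> DsSegment:
    """A duplex with exactly one ACC^U site (score-1 window) at ``i_top``.

    The backbone alternates over {A,G,U} (no C anywhere else), so neither
    strand can contain a second ACCU match; the 14-nt window around the
    bond is the preference model's fully preferred sequence.
    """
    backbone = ("AGU" * (length // 3 + 5))[:length]
    seq = list(backbone)
    # preferred window: residues i-6 .. i+7 (bond between window pos 7|8)
    seq[i_top - 7 : i_top + 7] = list("AAAGACCUCGAAAA")
    return DsSegment(id=seg_id, top_sequence="".join(seq))


@pytest.fixture
def single_site_segment234():
    """234-bp substrate cut once at bond 89 (the plasmid-derived window)."""
    return make_single_site_segment(234, 89)
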