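import numpy as np
import pytest

from pasedit import EditorSpec, PASMotifSpec, default_motifs, get_editor


@pytest.fixture(scope="session")
def editor() -> EditorSpec:
    return get_editor("spcas9-abemax")


@pytest.fixture(scope="session")
def motifs() -> tuple[PASMotifSpec, ...]:
    return default_motifs()


#: DUX4-like context: ATTAAA, a 14-nt spacer free of extra PAMs/motifs, TGG.
DUX4_LIKE = "ATTAAA" + "ATCATCATCATCAT" + "TGG"


@pytest.fixture(scope="session")
def dux4_like_seq() -> str:
    return DUX4_LIKE


def random_genome(seed: int, length: int, at_rich: bool = False) -> str:
    rng = np.random.default_rng(seed)
    p = [0.4, 0.1, 0.1, 0.4] if at_rich else None
    return "".join("ACGT"[i] for i in rng.choice(4, size=length, p=p))
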