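import numpy as np
import pytest
from hypothesis import settings

from triagonist import report, seqio

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def reference_panel():
    """The packaged 20-candidate reference panel as a DataFrame."""
    return report.reference_candidates()


@pytest.fixture(scope="session")
def panel_seqs(reference_panel):
    return [seqio.tokenize(s) for s in reference_panel["sequence"]]


@pytest.fixture(scope="session")
def standard_panel_rows(reference_panel, panel_seqs):
    """(row, TokenSeq) pairs for panel entries without modified residues."""
    out = []
    for (_, row), seq in zip(reference_panel.iterrows(), panel_seqs):
        if all(len(tok) == 1 for tok in seq):
            out.append((row, seq))
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_tokenseq(rng, min_len=5, max_len=40, nsaa_prob=0.1):
    """Random TokenSeq, occasionally containing bracketed NSAA tokens."""
    letters = sorted(seqio.STANDARD_AA)
    n = int(rng.integers(min_len, max_len + 1))
    tokens = []
    for _ in range(n):
        aa = letters[int(rng.integers(20))]
        u = rng.random()
        if u < nsaa_prob / 2:
            tokens.append(f"[d{aa}]")
        elif u < nsaa_prob:
            tokens.append("[K (yE-C16)]")
        else:
            tokens.append(aa)
    return seqio.TokenSeq(tuple(tokens))
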