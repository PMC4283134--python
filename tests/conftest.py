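import numpy as np
import pytest

from fgphase.sequence import MOTIF_CLASS_NAMES

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_classify(seq: str) -> dict[str, int]:
    """Independent window-by-window FG motif classifier.

    Scans every 2-mer and applies the context rules directly, longest
    context first, with explicit set membership.  Used as the oracle for
    the production classifier.
    """
    counts = {name: 0 for name in MOTIF_CLASS_NAMES}
    for i in range(len(seq) - 1):
        if seq[i] != "F" or seq[i + 1] != "G":
            continue
        prev2 = seq[i - 2 : i] if i >= 2 else None
        prev1 = seq[i - 1] if i >= 1 else None
        nxt = seq[i + 2] if i + 2 < len(seq) else None
        if prev1 == "G" and nxt == "Q":
            counts["GFGQ"] += 1
        elif prev2 == "GL":
            counts["GLFG"] += 1
        elif prev2 == "SL":
            counts["SLFG"] += 1
        elif prev2 == "PA":
            counts["PAFG"] += 1
        elif prev1 == "P":
            counts["PFG"] += 1
        elif prev1 in ("G", "A"):
            counts["(G/A)FG"] += 1
        elif prev1 in ("S", "T"):
            counts["(S/T)FG"] += 1
        else:
            counts["other FG"] += 1
    return counts


def random_fg_rich_sequence(rng: np.random.Generator, length: int) -> str:
    """Random sequence enriched in F and G so FG contexts are frequent."""
    probs = np.full(20, 0.03)
    probs[AA20.index("F")] = 0.15
    probs[AA20.index("G")] = 0.20
    probs[AA20.index("L")] = 0.06
    probs[AA20.index("S")] = 0.05
    probs = probs / probs.sum()
    return "".join(rng.choice(list(AA20), size=length, p=probs))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20150106)
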