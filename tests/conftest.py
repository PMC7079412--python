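import numpy as np
import pytest

from ecbench import Read
from ecbench._seq import random_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


def make_substitution_trio(rng, length, n_raw_errors, corrected_mode="true"):
    """Random (true, raw, corrected) trio with substitution events only.

    corrected_mode: 'true' (perfect tool), 'raw' (no-op tool), or 'mixed'
    (each raw error fixed / ignored / changed wrong with prob 1/3 each,
    plus a small rate of false corrections on clean bases).
    """
    true = random_sequence(length, rng)
    raw = list(true)
    positions = rng.choice(length, size=n_raw_errors, replace=False)
    alphabet = "ACGT"
    for p in positions:
        raw[p] = alphabet[(alphabet.index(raw[p]) + int(rng.integers(1, 4))) % 4]
    raw = "".join(raw)
    if corrected_mode == "true":
        corrected = true
    elif corrected_mode == "raw":
        corrected = raw
    else:
        corrected = list(raw)
        for p in positions:
            action = int(rng.integers(0, 3))
            if action == 0:
                corrected[p] = true[p]
            elif action == 2:
                choices = [b for b in alphabet if b not in (true[p], raw[p])]
                corrected[p] = choices[int(rng.integers(0, len(choices)))]
        clean = [i for i in range(length) if i not in set(int(x) for x in positions)]
        for i in clean:
            if rng.random() < 0.02:
                corrected[i] = alphabet[
                    (alphabet.index(corrected[i]) + int(rng.integers(1, 4))) % 4
                ]
        corrected = "".join(corrected)
    return true, raw, corrected


def positionwise_classify(true, raw, corrected):
    """Independent brute-force classifier for equal-length substitution-only
    trios: compare the three sequences column by column, no alignment."""
    assert len(true) == len(raw) == len(corrected)
    counts = {"TP": 0, "TN": 0, "FP": 0, "FN": 0, "FN_WRONG": 0}
    for t, r, c in zip(true, raw, corrected):
        if c == r:
            counts["TN" if r == t else "FN"] += 1
        elif c == t:
            counts["TP"] += 1
        elif r == t:
            counts["FP"] += 1
        else:
            counts["FN_WRONG"] += 1
    return counts


def reads_from(seqs, prefix="r"):
    return [Read(f"{prefix}{i}", s) for i, s in enumerate(seqs)]
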