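import numpy as np

from sundapop.popgen.alignment import SequenceAlignment


def make_alignment(seqs, pops=None, ids=None):
    n = len(seqs)
    if pops is None:
        pops = ["p1"] * n
    if ids is None:
        ids = [f"i{k}" for k in range(n)]
    return SequenceAlignment(list(seqs), ids, list(pops))


def random_configs(rng, n, k=15, scale=1.0, jitter=0.1):
    """Non-degenerate random landmark configurations (n, k, 2)."""
    base = rng.normal(size=(k, 2))
    return base[None] * scale + rng.normal(size=(n, k, 2)) * jitter
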