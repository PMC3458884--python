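"""Tamura-Nei (TN93) pairwise nucleotide distances.

TN93 corrects the raw proportion of differing sites for unequal base
frequencies and for distinct purine-transition, pyrimidine-transition and
transversion rates.  Base frequencies are estimated alignment-wide;
ambiguous positions (N or gap) are deleted pairwise.
"""

from __future__ import annotations

import numpy as np

from .alignment import SequenceAlignment, pair_site_counts

__all__ = ["SaturationError", "base_frequencies", "tn93_distance", "tn93_matrix"]


class SaturationError(ValueError):
    """The correction's logarithm argument is non-positive (saturated pair)."""


def base_frequencies(aln: SequenceAlignment) -> dict[str, float]:
    m = aln.matrix.view(np.uint8)
    freqs = {}
    total = 0
    for b in "ACGT":
        c = int((m == ord(b)).sum())
        freqs[b] = c
        total += c
    return {b: c / total for b, c in freqs.items()}


def tn93_distance(
    seq_i: str,
    seq_j: str,
    freqs: dict[str, float],
    pair_label: str | None = None,
) -> float:
    """TN93 distance between two aligned sequences.

    ``freqs`` are the alignment-wide base frequencies.  Raises
    :class:`SaturationError` when the observed divergence exceeds what the
    model can accommodate.
    """
    valid, _, p1_count, p2_count, q_count = pair_site_counts(seq_i, seq_j)
    if valid < 1:
        raise ValueError("no overlapping unambiguous sites")
    p1 = p1_count / valid  # A<->G proportion
    p2 = p2_count / valid  # C<->T proportion
    q = q_count / valid  # transversion proportion
    if p1 == 0 and p2 == 0 and q == 0:
        return 0.0
    ga, gc, gg, gt = freqs["A"], freqs["C"], freqs["G"], freqs["T"]
    gr, gy = ga + gg, gc + gt
    label = pair_label or "pair"
    if gr == 0 or gy == 0:
        raise ValueError(
            f"degenerate base composition (no purines or no pyrimidines); "
            f"TN93 undefined for {label}"
        )
    # terms vanish when a transition class is absent from the alignment
    k1 = 2.0 * ga * gg / gr
    k2 = 2.0 * gc * gt / gy
    k3 = 2.0 * (gr * gy - ga * gg * gy / gr - gc * gt * gr / gy)
    d = 0.0
    for k, p, g2 in ((k1, p1, 2.0 * gr), (k2, p2, 2.0 * gy)):
        if k == 0.0:
            if p > 0:
                raise ValueError(
                    f"transitions observed in a base class with zero frequency "
                    f"({label})"
                )
            continue
        w = 1.0 - p / k - q / g2
        if w <= 0.0:
            raise SaturationError(f"TN93 saturation for {label}")
        d += -k * np.log(w)
    w3 = 1.0 - q / (2.0 * gr * gy)
    if w3 <= 0.0:
        raise SaturationError(f"TN93 saturation for {label}")
    return float(d - k3 * np.log(w3))


def tn93_matrix(aln: SequenceAlignment) -> np.ndarray:
    """(n, n) TN93 distance matrix with alignment-wide base frequencies."""
    freqs = base_frequencies(aln)
    n = aln.n
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = tn93_distance(
                aln.sequences[i],
                aln.sequences[j],
                freqs,
                pair_label=f"{aln.ids[i]}/{aln.ids[j]}",
            )
            out[i, j] = out[j, i] = d
    return out
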