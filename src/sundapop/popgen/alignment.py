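"""Aligned COI sequences with population (site) assignment.

Sequences are stored uppercase over the alphabet {A, C, G, T, N, -}.  Sites
consisting only of gaps/N carry no information and are dropped on input.
Ambiguity handling downstream is pairwise deletion: a site enters a pairwise
comparison only when both sequences carry an unambiguous base there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID = set(b"ACGTN-")

__all__ = ["SequenceAlignment", "HaplotypeTable", "read_alignment",
           "collapse_haplotypes", "ts_tv_ratio", "write_fasta"]


@dataclass
class SequenceAlignment:
    sequences: list[str]
    ids: list[str]
    populations: list[str]

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValueError("alignment needs at least 2 sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        self.sequences = [s.upper() for s in self.sequences]
        for i, s in enumerate(self.sequences):
            bad = set(s.encode()) - VALID
            if bad:
                raise ValueError(
                    f"sequence {self.ids[i]!r}: invalid characters "
                    f"{sorted(chr(b) for b in bad)}"
                )

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def matrix(self) -> np.ndarray:
        """(n, L) byte matrix view of the alignment."""
        return np.frombuffer("".join(self.sequences).encode(), dtype="S1").reshape(
            self.n, self.length
        )

    def subset(self, populations: list[str] | str) -> "SequenceAlignment":
        if isinstance(populations, str):
            populations = [populations]
        keep = [i for i, p in enumerate(self.populations) if p in populations]
        if not keep:
            raise KeyError(f"no sequences for populations {populations}")
        return SequenceAlignment(
            [self.sequences[i] for i in keep],
            [self.ids[i] for i in keep],
            [self.populations[i] for i in keep],
        )

    @property
    def population_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)


def read_alignment(path, pop_map) -> SequenceAlignment:
    """Read a FASTA alignment plus an individual→population TSV.

    Columns of all-gap/all-N are removed (count logged).  Every record id
    must appear in the map (column ``individual`` or ``specimen_id``, with
    ``population`` or ``site``).
    """
    if not isinstance(pop_map, pd.DataFrame):
        pop_map = pd.read_csv(pop_map, sep="\t", dtype=str)
    idcol = "individual" if "individual" in pop_map.columns else "specimen_id"
    popcol = "population" if "population" in pop_map.columns else "site"
    mapping = dict(zip(pop_map[idcol], pop_map[popcol]))

    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
    missing = [i for i in ids if i not in mapping]
    if missing:
        raise KeyError(f"individuals missing from population map: {missing[:5]}")

    mat = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), -1)
    informative = ~np.all((mat == b"-") | (mat == b"N"), axis=0)
    dropped = int((~informative).sum())
    if dropped:
        logger.warning("dropped %d all-gap/all-N columns", dropped)
        mat = mat[:, informative]
        seqs = [row.tobytes().decode() for row in mat]
    return SequenceAlignment(seqs, ids, [mapping[i] for i in ids])


def write_fasta(aln: SequenceAlignment, fasta_path, map_path=None) -> None:
    with open(fasta_path, "w") as fh:
        for i, s in zip(aln.ids, aln.sequences):
            fh.write(f">{i}\n{s}\n")
    if map_path is not None:
        pd.DataFrame({"individual": aln.ids, "population": aln.populations}).to_csv(
            map_path, sep="\t", index=False
        )


@dataclass
class HaplotypeTable:
    haplotypes: list[str]  # representative sequences, N-resolved where possible
    counts: pd.DataFrame  # haplotype index x population
    members: list[list[str]]  # individual ids per haplotype

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @property
    def total_n(self) -> int:
        return int(self.counts.to_numpy().sum())

    def frequencies(self) -> np.ndarray:
        return self.counts.sum(axis=1).to_numpy() / self.total_n


def _compatible(a: str, b: str) -> bool:
    """True when the sequences differ only where one of them carries N."""
    for x, y in zip(a, b):
        if x != y and x != "N" and y != "N":
            return False
    return True


def _merge_rep(rep: str, new: str) -> str:
    """Fill N positions of the representative from the new sequence."""
    return "".join(y if x == "N" else x for x, y in zip(rep, new))


def collapse_haplotypes(aln: SequenceAlignment) -> HaplotypeTable:
    """Collapse identical sequences into haplotypes, cross-tabulated by site.

    Sequences differing only at N positions are merged (N matches any base);
    matching is greedy in input order against the running representative,
    whose Ns are progressively resolved.
    """
    pops = aln.population_names
    reps: list[str] = []
    members: list[list[str]] = []
    counts: list[dict[str, int]] = []
    for seq, ind, pop in zip(aln.sequences, aln.ids, aln.populations):
        for h, rep in enumerate(reps):
            if _compatible(rep, seq):
                reps[h] = _merge_rep(rep, seq)
                members[h].append(ind)
                counts[h][pop] = counts[h].get(pop, 0) + 1
                break
        else:
            reps.append(seq)
            members.append([ind])
            counts.append({pop: 1})
    table = pd.DataFrame(
        [[c.get(p, 0) for p in pops] for c in counts],
        columns=pops,
        index=[f"H{h + 1}" for h in range(len(reps))],
    )
    return HaplotypeTable(haplotypes=reps, counts=table, members=members)


_PURINES = (b"A"[0], b"G"[0])
_PYRIMIDINES = (b"C"[0], b"T"[0])


def pair_site_counts(si: str, sj: str) -> tuple[int, int, int, int, int]:
    """(valid_sites, transitions, A<->G, C<->T, transversions) for one pair.

    Sites where either sequence is N or '-' are excluded (pairwise deletion).
    """
    a = np.frombuffer(si.encode(), dtype=np.uint8)
    b = np.frombuffer(sj.encode(), dtype=np.uint8)
    ok = np.isin(a, np.frombuffer(b"ACGT", np.uint8)) & np.isin(
        b, np.frombuffer(b"ACGT", np.uint8)
    )
    a, b = a[ok], b[ok]
    diff = a != b
    ag = diff & np.isin(a, _PURINES) & np.isin(b, _PURINES)
    ct = diff & np.isin(a, _PYRIMIDINES) & np.isin(b, _PYRIMIDINES)
    ts = int(ag.sum() + ct.sum())
    tv = int(diff.sum()) - ts
    return int(ok.sum()), ts, int(ag.sum()), int(ct.sum()), tv


def ts_tv_ratio(aln: SequenceAlignment) -> float:
    """Pooled transition/transversion ratio over all sequence pairs.

    Counts are summed over pairs before the ratio is taken (a mean of
    per-pair ratios is undefined whenever a pair has zero transversions).
    Returns ``inf`` when no transversions are observed at all.
    """
    ts_total = tv_total = 0
    for i in range(aln.n):
        for j in range(i + 1, aln.n):
            _, ts, _, _, tv = pair_site_counts(aln.sequences[i], aln.sequences[j])
            ts_total += ts
            tv_total += tv
    if ts_total == 0 and tv_total == 0:
        raise ValueError("no differing sites in the alignment")
    if tv_total == 0:
        return float("inf")
    return ts_total / tv_total
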