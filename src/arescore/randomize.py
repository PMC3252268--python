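"""Null sequence sets: composition-matched permutations and concatemers.

Two controls are supported. The composition-matched set pools every
nucleotide of the input, permutes the pool once (seeded), and re-partitions
it into sequences whose lengths match the input exactly — so the total
A/U/G/C content and the length multiset are preserved without error. The
concatemer set draws whole sequences from a pool with replacement and
concatenates them to hit a list of target lengths, a harsher null that keeps
local sequence structure intact.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .core import SequenceRecord

__all__ = ["composition_matched_set", "concatemer_set"]


def composition_matched_set(
    records: Sequence[SequenceRecord],
    seed: int,
    id_prefix: str = "rand",
) -> list[SequenceRecord]:
    """Composition- and length-matched randomized control sequences.

    Every nucleotide of every input sequence goes into one pool; a seeded
    uniform permutation of the pool is cut into pieces whose lengths equal
    the input lengths, in input order. Nucleotides are drawn without
    replacement, so for each letter x, count(x) over the output equals
    count(x) over the input exactly.
    """
    if not records or all(len(r.seq) == 0 for r in records):
        raise ValueError("need at least one non-empty record")
    rng = np.random.default_rng(seed)
    pool = np.frombuffer("".join(r.seq.upper() for r in records).encode("ascii"), dtype="S1")
    pool = pool[rng.permutation(pool.size)]
    out: list[SequenceRecord] = []
    offset = 0
    for i, rec in enumerate(records):
        n = len(rec.seq)
        piece = pool[offset : offset + n].tobytes().decode("ascii")
        offset += n
        out.append(SequenceRecord(f"{id_prefix}_{i + 1}", piece))
    return out


def concatemer_set(
    pool_records: Sequence[SequenceRecord],
    target_lengths: Sequence[int],
    seed: int,
    id_prefix: str = "concat",
) -> list[SequenceRecord]:
    """Size-matched concatemer controls.

    For each target length, pool sequences are drawn uniformly with
    replacement and concatenated until the target is reached; the final
    fragment is truncated at its tail so each output length is exact.
    """
    pool = [r.seq for r in pool_records if len(r.seq) > 0]
    if not pool:
        raise ValueError("pool must contain at least one non-empty sequence")
    if any(t <= 0 for t in target_lengths):
        raise ValueError("target lengths must be positive")
    rng = np.random.default_rng(seed)
    out: list[SequenceRecord] = []
    for i, target in enumerate(target_lengths):
        parts: list[str] = []
        total = 0
        while total < target:
            s = pool[int(rng.integers(len(pool)))]
            parts.append(s)
            total += len(s)
        seq = "".join(parts)[:target]
        out.append(SequenceRecord(f"{id_prefix}_{i + 1}", seq))
    return out
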