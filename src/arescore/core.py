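"""Core ARE scoring: AUUUA pentamer scanning, AU-block detection, bonus rules.

The score of a sequence is built from three features of AU-rich elements
(AREs): the number of AUUUA pentamers (basal score, one point each by
default), the proximity between neighbouring pentamers (graded bonuses for
overlapping or closely spaced pairs), and the presence of pentamers inside
extended regions of high A+U content (AU-blocks, detected with a sliding
window). All weights and window thresholds are configurable through
:class:`ScoreConfig`; the defaults are the algorithm's standard setting.

Scoring is case-insensitive and treats T and U identically, so DNA and RNA
input give the same result. IUPAC ambiguity letters never match the pentamer
and count as non-AU in window content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PENTAMER = "AUUUA"

__all__ = [
    "PENTAMER",
    "ScoreConfig",
    "SequenceRecord",
    "PentamerHit",
    "AUBlock",
    "AREScoreResult",
    "find_pentamers",
    "find_au_blocks",
    "proximity_bonuses",
    "block_bonuses",
    "score_sequence",
    "score_batch",
]


@dataclass(frozen=True)
class ScoreConfig:
    """Tunable parameters of the scoring rule.

    Parameters
    ----------
    pentamer_value : float
        Points added to the basal score per AUUUA pentamer.
    overlap_bonus : float
        Bonus for a pair of neighbouring pentamers that overlap (gap < 0).
    gap0_3_bonus, gap4_6_bonus, gap7_9_bonus : float
        Bonuses for neighbouring pentamers separated by 0-3, 4-6 and 7-9
        intervening nucleotides; pairs 10 or more apart earn nothing.
    block_bonus : float
        Bonus per pentamer fully contained in an AU-block.
    block_word : int
        Sliding-window size (nt) used for AU-block detection.
    block_start_au : float
        A+U fraction a window must reach to open a block (default 80%).
    block_end_au : float
        A+U fraction below which the block ends (default 55%).
    """

    pentamer_value: float = 1.0
    overlap_bonus: float = 1.5
    gap0_3_bonus: float = 0.75
    gap4_6_bonus: float = 0.4
    gap7_9_bonus: float = 0.2
    block_bonus: float = 0.3
    block_word: int = 20
    block_start_au: float = 0.80
    block_end_au: float = 0.55

    def __post_init__(self) -> None:
        bonuses = (
            self.pentamer_value,
            self.overlap_bonus,
            self.gap0_3_bonus,
            self.gap4_6_bonus,
            self.gap7_9_bonus,
            self.block_bonus,
        )
        if any(b < 0 for b in bonuses):
            raise ValueError("all score values must be >= 0")
        if not (0 < self.block_end_au <= self.block_start_au <= 1):
            raise ValueError("require 0 < block_end_au <= block_start_au <= 1")
        if self.block_word < 5:
            raise ValueError("block_word must be >= 5")


@dataclass(frozen=True)
class SequenceRecord:
    """An identified nucleotide sequence (DNA or RNA alphabet, any case)."""

    id: str
    seq: str


@dataclass(frozen=True)
class PentamerHit:
    """An AUUUA occurrence; ``start`` is the 0-based offset of its first A."""

    start: int

    @property
    def end(self) -> int:
        return self.start + 5


@dataclass(frozen=True)
class AUBlock:
    """A maximal AU-rich region, 0-based half-open interval [start, end)."""

    start: int
    end: int

    def contains(self, hit: PentamerHit) -> bool:
        return self.start <= hit.start and hit.end <= self.end


@dataclass
class AREScoreResult:
    """Per-sequence score breakdown."""

    record_id: str
    length: int
    hits: list[PentamerHit] = field(default_factory=list)
    blocks: list[AUBlock] = field(default_factory=list)
    basal: float = 0.0
    proximity_bonus_total: float = 0.0
    block_bonus_total: float = 0.0

    @property
    def n_pentamers(self) -> int:
        return len(self.hits)

    @property
    def total(self) -> float:
        return self.basal + self.proximity_bonus_total + self.block_bonus_total


def normalize(seq: str) -> str:
    """Uppercase and convert T to U, mapping DNA input onto the RNA alphabet."""
    return seq.upper().replace("T", "U")


def find_pentamers(seq: str) -> list[PentamerHit]:
    """Return every AUUUA occurrence, including overlapping ones, in order.

    ``AUUUAUUUA`` yields hits at 0 and 4. Ambiguity letters never match.
    """
    s = normalize(seq)
    hits: list[PentamerHit] = []
    i = s.find(PENTAMER)
    while i != -1:
        hits.append(PentamerHit(i))
        i = s.find(PENTAMER, i + 1)
    return hits


def _window_au_fractions(s: str, word: int) -> np.ndarray:
    """A+U fraction of each ``word``-sized window of an already-normalized string."""
    is_au = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    is_au = ((is_au == ord("A")) | (is_au == ord("U"))).astype(np.intp)
    cum = np.concatenate(([0], np.cumsum(is_au)))
    return (cum[word:] - cum[:-word]) / word


def find_au_blocks(seq: str, cfg: ScoreConfig | None = None) -> list[AUBlock]:
    """Detect maximal AU-blocks with the open/extend/close window rule.

    A block opens at the start of the first window whose A+U fraction reaches
    ``block_start_au``; it keeps extending while the window starting at each
    subsequent position stays at or above ``block_end_au``; it closes at the
    end of the last qualifying window. Overlapping or abutting blocks are
    merged. Sequences shorter than the window return no blocks.
    """
    cfg = cfg or ScoreConfig()
    s = normalize(seq)
    w = cfg.block_word
    if len(s) < w:
        return []
    au = _window_au_fractions(s, w)
    opens = au >= cfg.block_start_au
    extends = au >= cfg.block_end_au

    raw: list[tuple[int, int]] = []
    in_block = False
    start = end = 0
    for i in range(au.size):
        if not in_block:
            if opens[i]:
                in_block = True
                start, end = i, i + w
        elif extends[i]:
            end = i + w
        else:
            raw.append((start, end))
            in_block = False
    if in_block:
        raw.append((start, end))

    merged: list[AUBlock] = []
    for b_start, b_end in raw:
        if merged and b_start <= merged[-1].end:
            merged[-1] = AUBlock(merged[-1].start, max(merged[-1].end, b_end))
        else:
            merged.append(AUBlock(b_start, b_end))
    return merged


_GAP_BANDS = (
    # (lo, hi, attr) — gap = nt strictly between two pentamers
    (0, 3, "gap0_3_bonus"),
    (4, 6, "gap4_6_bonus"),
    (7, 9, "gap7_9_bonus"),
)


def pair_bonus(gap: int, cfg: ScoreConfig) -> float:
    """Bonus for a neighbouring pentamer pair ``gap`` nucleotides apart."""
    if gap < 0:
        return cfg.overlap_bonus
    for lo, hi, attr in _GAP_BANDS:
        if lo <= gap <= hi:
            return getattr(cfg, attr)
    return 0.0


def proximity_bonuses(hits: Sequence[PentamerHit], cfg: ScoreConfig | None = None) -> float:
    """Sum of pair bonuses over consecutive pentamers (neighbours only).

    The gap is the number of nucleotides strictly between the two pentamers;
    a negative gap means they overlap. Only adjacent hits in position order
    contribute, so three tandem overlapping pentamers earn two overlap
    bonuses, not three.
    """
    cfg = cfg or ScoreConfig()
    return sum(
        pair_bonus(b.start - a.end, cfg) for a, b in zip(hits, hits[1:])
    )


def block_bonuses(
    hits: Sequence[PentamerHit],
    blocks: Sequence[AUBlock],
    cfg: ScoreConfig | None = None,
) -> float:
    """Bonus per pentamer whose full 5-nt span lies inside some AU-block."""
    cfg = cfg or ScoreConfig()
    return cfg.block_bonus * sum(
        1 for h in hits if any(b.contains(h) for b in blocks)
    )


def score_sequence(rec: SequenceRecord | str, cfg: ScoreConfig | None = None) -> AREScoreResult:
    """Score one sequence; accepts a :class:`SequenceRecord` or a bare string."""
    cfg = cfg or ScoreConfig()
    if isinstance(rec, str):
        rec = SequenceRecord("seq", rec)
    hits = find_pentamers(rec.seq)
    res = AREScoreResult(record_id=rec.id, length=len(rec.seq), hits=hits)
    res.blocks = find_au_blocks(rec.seq, cfg)
    if not hits:
        return res
    res.basal = len(hits) * cfg.pentamer_value
    res.proximity_bonus_total = proximity_bonuses(hits, cfg)
    res.block_bonus_total = block_bonuses(hits, res.blocks, cfg)
    return res


def score_batch(
    records: Iterable[SequenceRecord],
    cfg: ScoreConfig | None = None,
    min_len: int = 10,
) -> tuple[pd.DataFrame, list[str]]:
    """Score a set of records, excluding those shorter than ``min_len``.

    Returns a results table (one row per retained record, input order
    preserved) and the list of skipped record ids. Duplicate ids are an
    error: every downstream table is keyed by id.
    """
    cfg = cfg or ScoreConfig()
    records = list(records)
    seen: set[str] = set()
    dups = sorted({r.id for r in records if r.id in seen or seen.add(r.id)})
    if dups:
        raise ValueError(f"duplicate record ids: {', '.join(dups)}")
    skipped = [r.id for r in records if len(r.seq) < min_len]
    rows = []
    for rec in records:
        if len(rec.seq) < min_len:
            continue
        res = score_sequence(rec, cfg)
        rows.append(
            {
                "id": res.record_id,
                "length": res.length,
                "n_pentamers": res.n_pentamers,
                "n_blocks": len(res.blocks),
                "basal": res.basal,
                "proximity_bonus": res.proximity_bonus_total,
                "block_bonus": res.block_bonus_total,
                "arescore": res.total,
            }
        )
    columns = [
        "id",
        "length",
        "n_pentamers",
        "n_blocks",
        "basal",
        "proximity_bonus",
        "block_bonus",
        "arescore",
    ]
    return pd.DataFrame(rows, columns=columns), skipped
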