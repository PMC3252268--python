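"""Synthetic 3'UTR transcriptomes with planted AU-rich elements.

Generates a background of random 3'UTR-like sequences — log-normal length
distribution, fixed background A+U fraction — and plants, in a chosen
fraction of records, a class-II-like ARE cassette: a run of partially
overlapping AUUUA pentamers embedded in AU-only flanks so that the cassette
sits inside an AU-block. A truth table records which records carry a
cassette and where, so enrichment analyses can be checked against known
ground truth.

Defaults emulate a fly-like transcriptome: median 3'UTR length ~207 nt and
a background A+U content of 62%. The generator is fully reproducible from
its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SequenceRecord

__all__ = ["SyntheticTranscriptomeSpec", "generate_synthetic_transcriptome"]

_ALPHABET = np.array(list("AUGC"))


@dataclass(frozen=True)
class SyntheticTranscriptomeSpec:
    """Parameters of the synthetic transcriptome.

    Lengths are drawn log-normally with the given median and log-scale
    sigma, clipped to [min_length, max_length]. ``planted_fraction`` of the
    records receive an ARE cassette of ``pentamer_count`` (range, inclusive)
    pentamers; consecutive pentamers overlap by sharing their terminal A
    (tandem AUUUAUUUA...) with probability ``overlap_prob``, otherwise they
    are separated by a short AU-only spacer of ``spacing`` (range,
    inclusive) nucleotides. The cassette is wrapped in ``flank`` AU-only
    nucleotides on each side so it lies within an AU-block.
    """

    n_genes: int = 2000
    length_median: float = 207.0
    length_sigma: float = 0.7
    min_length: int = 10
    max_length: int = 5000
    background_au: float = 0.62
    planted_fraction: float = 0.05
    pentamer_count: tuple[int, int] = (4, 7)
    overlap_prob: float = 0.7
    spacing: tuple[int, int] = (0, 3)
    flank: int = 10
    seed: int = 0


def _max_cassette_len(spec: SyntheticTranscriptomeSpec) -> int:
    k = spec.pentamer_count[1]
    return 5 + (k - 1) * (5 + spec.spacing[1]) + 2 * spec.flank


def _cassette(spec: SyntheticTranscriptomeSpec, rng: np.random.Generator) -> tuple[str, int]:
    k = int(rng.integers(spec.pentamer_count[0], spec.pentamer_count[1] + 1))
    parts = ["AUUUA"]
    for _ in range(k - 1):
        if rng.random() < spec.overlap_prob:
            parts.append("UUUA")  # share the A: tandem overlap
        else:
            gap = int(rng.integers(spec.spacing[0], spec.spacing[1] + 1))
            parts.append("".join(rng.choice(["A", "U"], size=gap)) + "AUUUA")
    flank_l = "".join(rng.choice(["A", "U"], size=spec.flank))
    flank_r = "".join(rng.choice(["A", "U"], size=spec.flank))
    return flank_l + "".join(parts) + flank_r, k


def _background(n: int, au: float, rng: np.random.Generator) -> str:
    p = np.array([au / 2, au / 2, (1 - au) / 2, (1 - au) / 2])
    return "".join(rng.choice(_ALPHABET, size=n, p=p))


def generate_synthetic_transcriptome(
    spec: SyntheticTranscriptomeSpec,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Generate the records and a truth table.

    Truth columns: id, length, planted (bool), n_planted_pentamers,
    cassette_start (0-based; -1 when not planted). Planted records whose
    drawn length cannot hold the cassette are lengthened to cassette + 10 nt.
    """
    if not (0 <= spec.planted_fraction <= 1):
        raise ValueError("planted_fraction must be in [0, 1]")
    if not (0 < spec.background_au < 1):
        raise ValueError("background_au must be in (0, 1)")
    if spec.pentamer_count[0] < 1 or spec.pentamer_count[0] > spec.pentamer_count[1]:
        raise ValueError("pentamer_count range invalid")
    if _max_cassette_len(spec) > spec.max_length:
        raise ValueError("cassette cannot fit within max_length")

    rng = np.random.default_rng(spec.seed)
    mu = np.log(spec.length_median)
    lengths = np.clip(
        np.round(rng.lognormal(mu, spec.length_sigma, size=spec.n_genes)).astype(int),
        spec.min_length,
        spec.max_length,
    )
    n_planted = int(round(spec.planted_fraction * spec.n_genes))
    planted_idx = set(rng.choice(spec.n_genes, size=n_planted, replace=False).tolist())

    records: list[SequenceRecord] = []
    truth_rows = []
    for i in range(spec.n_genes):
        length = int(lengths[i])
        planted = i in planted_idx
        cassette_start = -1
        n_pent = 0
        if planted:
            cassette, n_pent = _cassette(spec, rng)
            if length < len(cassette) + 10:
                length = len(cassette) + 10
            seq = _background(length, spec.background_au, rng)
            cassette_start = int(rng.integers(0, length - len(cassette) + 1))
            seq = (
                seq[:cassette_start]
                + cassette
                + seq[cassette_start + len(cassette) :]
            )
        else:
            seq = _background(length, spec.background_au, rng)
        rec_id = f"synth_{i + 1:05d}"
        records.append(SequenceRecord(rec_id, seq))
        truth_rows.append(
            {
                "id": rec_id,
                "length": len(seq),
                "planted": planted,
                "n_planted_pentamers": n_pent,
                "cassette_start": cassette_start,
            }
        )
    return records, pd.DataFrame(truth_rows)
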