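"""Reference panel of 26 Drosophila SL2-cell mRNAs with measured half-lives.

This built-in dataset holds, for each transcript: its half-life in minutes
under control (GFP dsRNA) and Tis11-knockdown conditions — slow decays are
right-censored at 240 min — its 3'UTR length, its ARE score, and whether it
belongs to the Tis11-sensitive group (up-regulated on Tis11 knockdown) or
the control group. Twelve transcripts are Tis11-sensitive, fourteen are
controls. The panel drives the desk-scale validation analyses: score-bin
counts, the stability of score-zero transcripts, rank correlations of score
and 3'UTR length against half-life, and ROC discrimination of labile
(half-life < 140 min) from stable (censored > 240 min) transcripts.
"""

from __future__ import annotations

import pandas as pd

from .stats import roc_auc, spearman

__all__ = [
    "load_table1",
    "score_bin_counts",
    "score_zero_censored_count",
    "correlations",
    "labile_stable_roc",
    "table1_report",
    "LABILE_MAX_MIN",
    "CENSOR_LIMIT_MIN",
]

LABILE_MAX_MIN = 140.0
CENSOR_LIMIT_MIN = 240.0

# name, group, half-life (GFP), censored?, half-life (Tis11 kd), censored?,
# 3'UTR length (nt), ARE score
_ROWS = [
    ("Pxn",        "tis11_sensitive", 163.0, False, 510.0, True,  180,  0.0),
    ("TotA",       "tis11_sensitive", None,  True,  None,  True,  153,  2.6),
    ("Vir-1",      "tis11_sensitive", None,  True,  None,  True,  311,  4.0),
    ("Lectin-28C", "tis11_sensitive", None,  True,  None,  True,  53,   0.0),
    ("CG8239",     "tis11_sensitive", 134.0, False, 199.0, False, 287,  10.8),
    ("NimB2",      "tis11_sensitive", None,  True,  None,  True,  81,   0.0),
    ("Ric",        "tis11_sensitive", 229.0, False, 200.0, False, 1317, 10.1),
    ("CG15435",    "tis11_sensitive", 46.0,  False, 60.0,  False, 191,  11.55),
    ("CG7115",     "tis11_sensitive", 63.0,  False, 85.0,  False, 493,  6.15),
    ("CG10249",    "tis11_sensitive", 49.0,  False, 44.0,  False, 822,  6.5),
    ("CG2915",     "tis11_sensitive", None,  True,  None,  True,  83,   0.0),
    ("NimB1",      "tis11_sensitive", None,  True,  None,  True,  36,   0.0),
    ("Reck",       "control",         39.0,  False, 35.0,  False, 582,  11.2),
    ("Pax",        "control",         158.0, False, 120.0, False, 325,  4.65),
    ("CG32512",    "control",         114.0, False, 78.0,  False, 583,  9.55),
    ("Ho",         "control",         77.0,  False, 65.0,  False, 104,  4.1),
    ("CG5026",     "control",         183.0, False, 128.0, False, 572,  6.5),
    ("CG7787",     "control",         None,  True,  168.0, False, 438,  3.2),
    ("Ef1a48D",    "control",         None,  True,  None,  True,  554,  4.9),
    ("CG17184",    "control",         66.0,  False, 107.0, False, 653,  3.9),
    ("CG31997",    "control",         None,  True,  None,  True,  70,   0.0),
    ("CG10131",    "control",         None,  True,  None,  True,  97,   0.0),
    ("CG8135",     "control",         None,  True,  170.0, False, 148,  0.0),
    ("dUTPase",    "control",         None,  True,  None,  True,  131,  0.0),
    ("Mod(mdg4)",  "control",         93.0,  False, 74.0,  False, 44,   5.2),
    ("eEF1d",      "control",         None,  True,  None,  True,  91,   0.0),
]


def load_table1() -> pd.DataFrame:
    """The 26-transcript panel as a DataFrame.

    Columns: name, group, half_life_gfp (min; NaN when censored),
    censored_gfp, half_life_tis11, censored_tis11, utr_length (nt), arescore.
    """
    df = pd.DataFrame(
        _ROWS,
        columns=[
            "name",
            "group",
            "half_life_gfp",
            "censored_gfp",
            "half_life_tis11",
            "censored_tis11",
            "utr_length",
            "arescore",
        ],
    )
    return df


def score_bin_counts(df: pd.DataFrame | None = None) -> dict[str, int]:
    """Counts of panel transcripts with low (<4), medium (4-7.99) and high (>=8) scores."""
    df = load_table1() if df is None else df
    s = df["arescore"]
    return {
        "lt4": int((s < 4).sum()),
        "4_to_8": int(((s >= 4) & (s < 8)).sum()),
        "ge8": int((s >= 8).sum()),
    }


def score_zero_censored_count(df: pd.DataFrame | None = None) -> tuple[int, int]:
    """(number of score-0 transcripts whose control half-life is censored, number of score-0 transcripts)."""
    df = load_table1() if df is None else df
    zero = df[df["arescore"] == 0]
    return int(zero["censored_gfp"].sum()), len(zero)


def correlations(df: pd.DataFrame | None = None) -> dict[str, float]:
    """Spearman of score and of 3'UTR length against the control half-life.

    Censored half-lives enter as mutual ties above all measured values.
    """
    df = load_table1() if df is None else df
    cens = df["censored_gfp"].tolist()
    hl = df["half_life_gfp"].fillna(CENSOR_LIMIT_MIN).tolist()
    return {
        "score_vs_half_life": spearman(df["arescore"], hl, y_censored=cens),
        "length_vs_half_life": spearman(df["utr_length"], hl, y_censored=cens),
    }


def labile_stable_roc(df: pd.DataFrame | None = None) -> dict[str, object]:
    """ROC of score and of 3'UTR length for labile vs stable transcripts.

    Labile: measured half-life < 140 min. Stable: censored > 240 min.
    Transcripts in between are excluded.
    """
    df = load_table1() if df is None else df
    labile = df[(~df["censored_gfp"]) & (df["half_life_gfp"] < LABILE_MAX_MIN)]
    stable = df[df["censored_gfp"]]
    return {
        "n_labile": len(labile),
        "n_stable": len(stable),
        "score_roc": roc_auc(labile["arescore"], stable["arescore"]),
        "length_roc": roc_auc(labile["utr_length"], stable["utr_length"]),
    }


def table1_report() -> dict[str, object]:
    """The full analysis bundle over the built-in panel."""
    df = load_table1()
    n_censored, n_zero = score_zero_censored_count(df)
    roc = labile_stable_roc(df)
    return {
        "n_rows": len(df),
        "bin_counts": score_bin_counts(df),
        "score_zero_censored": n_censored,
        "score_zero_total": n_zero,
        "correlations": correlations(df),
        "n_labile": roc["n_labile"],
        "n_stable": roc["n_stable"],
        "score_auc": roc["score_roc"].auc,
        "length_auc": roc["length_roc"].auc,
    }
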