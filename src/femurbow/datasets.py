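"""Packaged transcription of the study's published measurement tables.

The study measured ten lateral femur radiographs (five women, five men),
each three times for the cortical outline and three times for the medullary
canal, and published per-subject mean radii (mm) for the whole shaft and its
proximal, middle and distal thirds, for both structures.

Column-label note: in the per-subject table as printed, the "Proximal" and
"Distal" column labels are interchanged relative to the grouped-summary
table — the pooled means only reconcile under the swap (the printed
"Proximal Outer" column pools to the summary's *distal* outline mean, and
vice versa).  :func:`subject_table` therefore returns the reconciled
(canonical) labeling by default; ``canonical=False`` returns the columns
exactly as printed.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["subject_table", "published_summary"]

# Per-subject radii (mm) exactly as printed: one row per subject, columns
# labeled as in the source table ("outer" = cortical outline, "inner" =
# medullary canal).  Each value is that subject's mean over 3 repeats.
_TABLE1_CSV = """\
age,sex,whole_outer,whole_inner,proximal_outer,proximal_inner,middle_outer,middle_inner,distal_outer,distal_inner
24,F,1631,1883,340,811,1883,1404,653,671
27,F,1338,1600,379,1043,1546,1577,983,712
38,F,1105,982,311,632,1089,967,673,452
20,F,1730,1604,432,574,1671,1520,1041,693
31,F,1299,1183,770,1005,1193,1217,604,629
37,M,1696,1614,392,632,1486,1812,907,871
40,M,1087,899,436,696,1179,1172,746,1032
43,M,1094,1117,379,795,1418,1166,1098,905
57,M,1112,1038,534,758,1068,1117,715,693
27,M,1330,1019,550,510,1413,1676,558,405
"""

# Grouped summary as printed (mm, mean and SD), with the canonical
# (reconciled) part labels.
PUBLISHED_SUMMARY = {
    ("whole", "total"): (1318, 297),
    ("whole", "outline"): (1342, 252),
    ("whole", "canal"): (1294, 338),
    ("whole", "men"): (1201, 257),
    ("whole", "women"): (1435, 291),
    ("proximal", "total"): (752, 212),
    ("proximal", "outline"): (798, 210),
    ("proximal", "canal"): (706, 208),
    ("proximal", "men"): (793, 227),
    ("proximal", "women"): (711, 192),
    ("middle", "total"): (1379, 288),
    ("middle", "outline"): (1394, 285),
    ("middle", "canal"): (1363, 294),
    ("middle", "men"): (1351, 277),
    ("middle", "women"): (1407, 300),
    ("distal", "total"): (599, 220),
    ("distal", "outline"): (452, 133),
    ("distal", "canal"): (746, 190),
    ("distal", "men"): (568, 161),
    ("distal", "women"): (630, 266),
}


def subject_table(canonical: bool = True) -> pd.DataFrame:
    """Per-subject published radii in wide form, one row per subject.

    With ``canonical=True`` (default) the proximal/distal columns carry the
    reconciled labels (see module docstring); with ``canonical=False`` the
    columns are exactly as printed.
    """
    df = pd.read_csv(io.StringIO(_TABLE1_CSV))
    df.insert(0, "subject", [f"S{i+1:02d}" for i in range(len(df))])
    if canonical:
        df = df.rename(
            columns={
                "proximal_outer": "distal_outer",
                "proximal_inner": "distal_inner",
                "distal_outer": "proximal_outer",
                "distal_inner": "proximal_inner",
            }
        )
        order = [
            "subject", "age", "sex",
            "whole_outer", "whole_inner",
            "proximal_outer", "proximal_inner",
            "middle_outer", "middle_inner",
            "distal_outer", "distal_inner",
        ]
        df = df[order]
    return df


def subject_table_long(canonical: bool = True) -> pd.DataFrame:
    """The per-subject table in long form: one row per subject x structure.

    Columns: subject, age, sex, structure ("outline"/"canal") and the four
    radius columns whole_mm/proximal_mm/middle_mm/distal_mm.  This is the
    layout the reliability/aggregation functions consume (here with a single
    published per-subject value standing for the subject's repeat mean).
    """
    wide = subject_table(canonical=canonical)
    frames = []
    for suffix, structure in (("outer", "outline"), ("inner", "canal")):
        sub = wide[["subject", "age", "sex"]].copy()
        sub["structure"] = structure
        for part in ("whole", "proximal", "middle", "distal"):
            sub[f"{part}_mm"] = wide[f"{part}_{suffix}"].to_numpy(dtype=float)
        frames.append(sub)
    return pd.concat(frames, ignore_index=True)


def published_summary() -> pd.DataFrame:
    """The printed grouped summary (mean, SD in mm) as a tidy frame."""
    rows = [
        {"part": part, "group": group, "mean_mm": m, "sd_mm": s}
        for (part, group), (m, s) in PUBLISHED_SUMMARY.items()
    ]
    return pd.DataFrame(rows)
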