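"""Reference fraction table and the reporting-convention check.

These are the published per-construct event counts of the tether assay: how
many stably recruited Mcm2-7 events reached the high-FRET (Orc6 tether)
state, and how ORC retention after Cdt1 release distributes across fast
release (within three frames, 7.8 s) and long retention (beyond 100 s).
``reproduce_worked_examples`` recomputes every percentage +/- SE from its raw
(k, n) counts through :func:`orctether.kinetics.fraction_se` and checks the
formatted result against the expected string, validating the binomial SE
model and the two-stage rounding convention end to end.
"""

from __future__ import annotations

import pandas as pd

from .kinetics import fraction_se

__all__ = ["WORKED_EXAMPLES", "reproduce_worked_examples"]

# (label, kind, k, n, expected string); kind "formation" prints one decimal
# without SE, kind "fraction" prints integer percent with integer SE.
WORKED_EXAMPLES: list[tuple[str, str, int, int, str]] = [
    ("tether formation, wild-type ORC", "formation", 184, 201, "91.5%"),
    ("tether formation, Orc6 dN", "formation", 102, 124, "82.3%"),
    ("tether formation, Orc6 dN + lnk1scr", "formation", 5, 115, "4.4%"),
    ("tether formation, CDK-phosphorylated ORC", "formation", 77, 143, "53.9%"),
    ("released within 7.8 s of Cdt1 release, Orc6 dN", "fraction", 85, 106, "80 ± 4%"),
    ("released within 7.8 s of Cdt1 release, Orc6 dN + lnk1scr", "fraction", 88, 106, "83 ± 4%"),
    ("released within 7.8 s of Cdt1 release, wild-type ORC", "fraction", 58, 147, "39 ± 4%"),
    ("retained > 100 s after Cdt1 release, wild-type ORC", "fraction", 35, 147, "24 ± 4%"),
    ("released within 7.8 s of Cdt1 release, Orc6 lnk1scr", "fraction", 66, 104, "63 ± 5%"),
    ("retained > 100 s after Cdt1 release, Orc6 lnk1scr", "fraction", 13, 104, "13 ± 3%"),
]


def format_case(kind: str, k: int, n: int) -> str:
    fs = fraction_se(k, n)
    if kind == "formation":
        return fs.as_string(decimals=1, with_se=False)
    return fs.as_string(decimals=0, with_se=True)


def reproduce_worked_examples(
    table: list[tuple[str, str, int, int, str]] | None = None,
) -> pd.DataFrame:
    """Recompute each reference fraction from (k, n) and compare strings."""
    rows = []
    for label, kind, k, n, expected in table or WORKED_EXAMPLES:
        computed = format_case(kind, k, n)
        rows.append(
            dict(
                label=label,
                k=k,
                n=n,
                computed=computed,
                expected=expected,
                ok=computed == expected,
            )
        )
    return pd.DataFrame(rows)
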