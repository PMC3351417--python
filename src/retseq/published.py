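"""Access to the published fold-change tables shipped with the package.

Each table lists, per transcript, the fold magnitude (with a ``(down)``
flag for decreases) for three contrasts against nondiabetic controls:
diabetic (D_vs_N), diabetic treated with the RAGE inhibitor (T1_vs_N),
and diabetic treated with the p38 MAPK inhibitor (T2_vs_N).
"""

from __future__ import annotations

import re
from importlib import resources

import pandas as pd

TABLE_NAMES = (
    "crystallins",
    "wnt",
    "microvasculature",
    "inflammation",
    "apoptosis",
    "neuronal",
    "photoreceptor",
    "ugt",
)

_FOLD_RE = re.compile(r"^\s*([0-9]+(?:\.[0-9]+)?)\s*(?:\((down)\))?\s*$")

_CONTRAST_COLS = {"D_vs_N": "D", "T1_vs_N": "T1", "T2_vs_N": "T2"}


def parse_directional_fold(text: str) -> tuple[float, str]:
    """Parse a printed fold entry like ``"2.4"`` or ``"1.5 (down)"`` into
    a (ratio, direction) pair."""
    match = _FOLD_RE.match(str(text))
    if not match:
        raise ValueError(f"cannot parse fold entry {text!r}")
    ratio = float(match.group(1))
    if ratio < 1:
        raise ValueError(f"fold magnitude must be >= 1, got {ratio}")
    return ratio, "down" if match.group(2) else "up"


def format_directional_fold(ratio: float, direction: str) -> str:
    text = f"{ratio:g}"
    return f"{text} (down)" if direction == "down" else text


def load_fold_table(name: str) -> pd.DataFrame:
    """Load one published table by name (see ``TABLE_NAMES``).

    Returns a DataFrame indexed by gene symbol with ``gene_name`` plus,
    per contrast, ``ratio_<c>`` and ``dir_<c>`` columns and the original
    printed entry ``printed_<c>``.
    """
    if name not in TABLE_NAMES:
        raise KeyError(f"unknown table {name!r}; choose from {TABLE_NAMES}")
    ref = resources.files("retseq.data").joinpath(f"{name}.tsv")
    with ref.open("r") as handle:
        raw = pd.read_csv(handle, sep="\t", comment="#", dtype=str)
    out = raw[["gene_symbol", "gene_name"]].copy()
    for col, tag in _CONTRAST_COLS.items():
        parsed = raw[col].map(parse_directional_fold)
        out[f"ratio_{tag}"] = [p[0] for p in parsed]
        out[f"dir_{tag}"] = [p[1] for p in parsed]
        out[f"printed_{tag}"] = raw[col]
    return out.set_index("gene_symbol")


def load_all_fold_tables() -> dict[str, pd.DataFrame]:
    return {name: load_fold_table(name) for name in TABLE_NAMES}
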