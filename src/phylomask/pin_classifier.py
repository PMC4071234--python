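"""Classify PIN proteins into the five structural morphology types.

A PIN protein is summarised by its length and its predicted transmembrane
domain (TMD) intervals.  The central hydrophilic loop is the largest gap
between consecutive TMDs; the TMDs before it form the N-terminal block and
those after it the C-terminal block.  Types:

1. long    — both TMD blocks present, long central loop;
2. short   — both blocks present, short loop;
3. reduced — both blocks present, intermediate loop;
4. C-terminal TMD only — every TMD sits in the C-terminal part;
5. N-terminal TMD only — every TMD sits in the N-terminal part.

The defining criteria are structural; the numeric cutoffs (loop length
thresholds, the terminal fraction) are configuration, exposed in
:class:`ClassifierConfig`.  TMD intervals — not counts — are the canonical
input: a TMD count alone cannot separate the types (five TMDs occur in types
1, 2, 4 and 5 alike).  Known override assignments (gene families where the
TMD prediction is doubted and the sequence shows no other difference from
long forms) are applied last and logged in the output.

All interval coordinates are 1-based inclusive, as in biologist-facing
tables.  TMD predictions are hypotheses pending structural confirmation; the
output metadata carries that disclaimer.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

DISCLAIMER = (
    "TMD layouts are predicted protein domains; classifications await "
    "confirmation of the tertiary structure."
)

#: The two published override assignments: predicted N-terminal-TMD-only but
#: otherwise indistinguishable from long forms, so coded long (type 1).
DEFAULT_OVERRIDES: dict[str, int] = {"OsPIN3a": 1, "Aco018694": 1}


@dataclass(frozen=True)
class ClassifierConfig:
    """Numeric cutoffs for the structural criteria (amino acids)."""

    long_loop_min: int = 200
    reduced_loop_min: int = 100
    terminal_fraction: float = 0.5
    min_block_tmds: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.reduced_loop_min < self.long_loop_min:
            raise ValueError("need 0 < reduced_loop_min < long_loop_min")
        if not 0 < self.terminal_fraction < 1:
            raise ValueError("terminal_fraction must be in (0, 1)")


@dataclass
class PinRecord:
    """One protein: length, sorted non-overlapping TMD intervals, type."""

    identifier: str
    protein_length: int
    tmds: list[tuple[int, int]]
    type: Optional[int] = None
    override: Optional[tuple[int, str]] = None

    def __post_init__(self) -> None:
        self.tmds = sorted((int(a), int(b)) for a, b in self.tmds)
        prev_end = 0
        for (a, b) in self.tmds:
            if not (1 <= a <= b <= self.protein_length):
                raise ValueError(
                    f"{self.identifier}: TMD {a}-{b} outside 1-{self.protein_length}"
                )
            if a <= prev_end:
                raise ValueError(f"{self.identifier}: overlapping TMDs")
            prev_end = b


def classify_pin(
    rec: PinRecord,
    cfg: ClassifierConfig = ClassifierConfig(),
    overrides: Optional[Mapping[str, int]] = None,
) -> tuple[Optional[int], dict]:
    """Assign a morphology type 1-5 and return it with derived features.

    Features: ``loop_length`` (largest inter-TMD gap), ``n_tmd_nblock`` /
    ``n_tmd_cblock`` (TMDs before/after that gap), ``override_applied``.
    Zero TMDs yields ``(None, ...)`` — unassigned.
    """
    features: dict = {"disclaimer": DISCLAIMER, "override_applied": False}
    if not rec.tmds:
        features.update(loop_length=0, n_tmd_nblock=0, n_tmd_cblock=0)
        return None, features
    L = rec.protein_length
    tf = cfg.terminal_fraction
    # central loop = largest gap between consecutive TMDs
    loop_length, split_after = 0, len(rec.tmds)
    for i in range(len(rec.tmds) - 1):
        gap = rec.tmds[i + 1][0] - rec.tmds[i][1] - 1
        if gap > loop_length:
            loop_length, split_after = gap, i + 1
    n_block = rec.tmds[:split_after]
    c_block = rec.tmds[split_after:]
    features.update(
        loop_length=loop_length,
        n_tmd_nblock=len(n_block),
        n_tmd_cblock=len(c_block),
    )
    if not c_block or all(b <= tf * L for (_, b) in rec.tmds):
        ptype = 5
    elif not n_block or all(a > (1 - tf) * L for (a, _) in rec.tmds):
        ptype = 4
    elif loop_length >= cfg.long_loop_min:
        ptype = 1
    elif loop_length >= cfg.reduced_loop_min:
        ptype = 3
    else:
        ptype = 2
    if overrides and rec.identifier in overrides:
        forced = int(overrides[rec.identifier])
        if forced != ptype:
            features["override_applied"] = True
            features["structural_type"] = ptype
            ptype = forced
    return ptype, features


def parse_intervals(text: str) -> list[tuple[int, int]]:
    """Parse ``"12-34;56-78"`` into interval pairs (1-based inclusive)."""
    out = []
    for chunk in str(text).split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        m = re.fullmatch(r"(\d+)\s*-\s*(\d+)", chunk)
        if not m:
            raise ValueError(f"bad interval {chunk!r}")
        out.append((int(m.group(1)), int(m.group(2))))
    if not out:
        raise ValueError(
            "no TMD intervals given; counts alone cannot separate the types"
        )
    return out


def classify_table(
    df: pd.DataFrame,
    cfg: ClassifierConfig = ClassifierConfig(),
    overrides: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Classify a table with columns id, length, tmd_intervals."""
    rows = []
    for _, row in df.iterrows():
        rec = PinRecord(
            identifier=str(row["id"]),
            protein_length=int(row["length"]),
            tmds=parse_intervals(row["tmd_intervals"]),
        )
        ptype, feats = classify_pin(rec, cfg, overrides)
        rows.append(
            {
                "id": rec.identifier,
                "length": rec.protein_length,
                "tmd_intervals": row["tmd_intervals"],
                "type": ptype,
                "loop_length": feats["loop_length"],
                "n_tmd_nblock": feats["n_tmd_nblock"],
                "n_tmd_cblock": feats["n_tmd_cblock"],
                "override_applied": feats["override_applied"],
            }
        )
    return pd.DataFrame(rows)


def load_reference_table() -> pd.DataFrame:
    """The packaged PIN gene table: terminal name, protein length, TMD count,
    printed morphology score, and the geometry score actually predicted
    (differing from the printed score only for the two override genes)."""
    ref = importlib.resources.files("phylomask.data") / "pin_table1.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
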