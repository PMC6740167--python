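"""Utility scoring of five-dimension health-status responses.

A response gives a level 1..5 on each of mobility, self-care, usual
activities, pain/discomfort and anxiety/depression.  A value set maps the
response to a single utility index anchored at 1 (full health) and 0,
computed as the full-health constant minus per-dimension, per-level
decrements; values below 0 (states worse than death) are permitted.

National value sets are licensed and must be supplied by the user as a
decrement CSV.  A clearly labelled synthetic "toy" value set is packaged so
the pipeline runs end-to-end without licensed content.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = ["DIMENSIONS", "ValueSet", "toy_value_set", "load_value_set", "utility"]

DIMENSIONS = ("mobility", "selfcare", "activities", "pain", "anxiety")


class ValueSetError(ValueError):
    pass


@dataclasses.dataclass
class ValueSet:
    """Per-dimension, per-level utility decrements plus a full-health constant.

    ``decrements[dim][level-1]`` is subtracted from the constant; level 1
    (no problems) must carry a zero decrement in every dimension so that the
    all-ones state scores exactly the constant.
    """

    decrements: dict
    full_health: float = 1.0

    def validate(self) -> None:
        for dim in DIMENSIONS:
            if dim not in self.decrements:
                raise ValueSetError(f"value set missing dimension {dim!r}")
            d = np.asarray(self.decrements[dim], dtype=float)
            if d.shape != (5,):
                raise ValueSetError(f"{dim}: need 5 per-level decrements")
            if d[0] != 0.0:
                raise ValueSetError(f"{dim}: level-1 decrement must be 0")


def toy_value_set() -> ValueSet:
    """A synthetic value set for demonstrations and tests.

    The decrements are invented (monotone in level, loosely shaped like
    published tariffs); they are NOT a licensed national tariff and carry no
    population meaning.
    """
    return ValueSet(
        decrements={
            "mobility": [0.0, 0.05, 0.09, 0.21, 0.34],
            "selfcare": [0.0, 0.05, 0.08, 0.16, 0.21],
            "activities": [0.0, 0.05, 0.08, 0.16, 0.22],
            "pain": [0.0, 0.06, 0.08, 0.28, 0.39],
            "anxiety": [0.0, 0.07, 0.12, 0.26, 0.38],
        },
        full_health=1.0,
    )


def load_value_set(path) -> ValueSet:
    """Read a value set CSV: rows (dimension, level, decrement).

    A row with dimension 'full_health' (level ignored) sets the constant.
    """
    df = pd.read_csv(path)
    need = {"dimension", "level", "decrement"}
    if not need.issubset(df.columns):
        raise ValueSetError(f"value-set file needs columns {sorted(need)}")
    full = 1.0
    dec: dict = {dim: [0.0] * 5 for dim in DIMENSIONS}
    for _, row in df.iterrows():
        dim = str(row["dimension"])
        if dim == "full_health":
            full = float(row["decrement"])
            continue
        if dim not in DIMENSIONS:
            raise ValueSetError(f"unknown dimension {dim!r}")
        lvl = int(row["level"])
        if not 1 <= lvl <= 5:
            raise ValueSetError(f"{dim}: level {lvl} outside 1..5")
        dec[dim][lvl - 1] = float(row["decrement"])
    vs = ValueSet(decrements=dec, full_health=full)
    vs.validate()
    return vs


def utility(response, value_set: ValueSet) -> float:
    """Utility index of one response: constant minus the five decrements.

    ``response`` is a length-5 sequence of levels (1..5) in dimension order.
    The result may be negative for severe states.
    """
    value_set.validate()
    response = list(response)
    if len(response) != 5:
        raise ValueError(f"expected 5 levels, got {len(response)}")
    total = value_set.full_health
    for dim, lvl in zip(DIMENSIONS, response):
        lvl = int(lvl)
        if not 1 <= lvl <= 5:
            raise ValueError(f"{dim}: level {lvl} outside 1..5")
        total -= value_set.decrements[dim][lvl - 1]
    return float(total)
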