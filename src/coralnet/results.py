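"""Shared result containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COLUMNS = ["term", "df", "statistic", "effect_size", "p_value", "p_adjusted"]


@dataclass
class TermTable:
    """Per-model-term df, statistic, effect size and p-values.

    Houses PERMANOVA (pseudo-F, R^2), ANCOVA (F, eta^2) and chi-square
    outputs alike; `statistic_name`/`effect_name` record which is which.
    """

    frame: pd.DataFrame
    statistic_name: str = "F"
    effect_name: str = "R2"

    def __post_init__(self) -> None:
        for col in COLUMNS:
            if col not in self.frame.columns:
                self.frame[col] = np.nan
        self.frame = self.frame[COLUMNS].reset_index(drop=True)

    def to_frame(self) -> pd.DataFrame:
        return self.frame.copy()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **kw) -> "TermTable":
        return cls(pd.read_csv(path), **kw)

    def __getitem__(self, term: str) -> pd.Series:
        row = self.frame[self.frame["term"] == term]
        if row.empty:
            raise KeyError(term)
        return row.iloc[0]

    def __eq__(self, other) -> bool:
        if not isinstance(other, TermTable):
            return NotImplemented
        a, b = self.frame, other.frame
        if list(a["term"]) != list(b["term"]):
            return False
        num = ["df", "statistic", "effect_size", "p_value", "p_adjusted"]
        return bool(
            np.allclose(
                a[num].to_numpy(dtype=float),
                b[num].to_numpy(dtype=float),
                equal_nan=True,
            )
        )

    def summary(self) -> str:
        hdr = f"{'term':<28}{'df':>5}{self.statistic_name:>10}{self.effect_name:>9}{'p':>9}{'p_adj':>9}"
        lines = [hdr, "-" * len(hdr)]
        for _, r in self.frame.iterrows():
            p_adj = "" if pd.isna(r["p_adjusted"]) else f"{r['p_adjusted']:9.4f}"
            p = "" if pd.isna(r["p_value"]) else f"{r['p_value']:9.4f}"
            stat = "" if pd.isna(r["statistic"]) else f"{r['statistic']:10.3f}"
            eff = "" if pd.isna(r["effect_size"]) else f"{r['effect_size']:9.4f}"
            lines.append(f"{r['term']:<28}{int(r['df']):>5}{stat}{eff}{p}{p_adj}")
        return "\n".join(lines)
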