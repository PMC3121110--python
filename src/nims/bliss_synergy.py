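"""Bliss-independence expectations and the MIIR synergy statistic.

For two inhibitors with single-agent inhibition fractions IR1 and IR2, the
Bliss independence model predicts a combined inhibition of

    IR_add = IR1 + IR2 − IR1·IR2.

The experimental synergy readout is the Maximum Increased Inhibition Rate,
MIIR = max over doses of (IR_syn − IR_add): how far the observed combination
exceeds the additive expectation at its best dose.  Dose–response tables use
a fixed dose ratio between the two agents (IC50-ratio design).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DoseResponseTable",
    "bliss_additive",
    "miir",
    "effective_combination_filter",
    "load_dose_response",
]

EFFECTIVE_THRESHOLD = 0.70


@dataclass
class DoseResponseTable:
    """Per-dose inhibition rates for two single agents and their combination.

    All rates are fractions in [0, 1]; rows keep a constant dose1:dose2
    ratio.  Percentage-scale input (any rate above 1) is converted with a
    warning.
    """

    dose1: np.ndarray
    dose2: np.ndarray
    ir1: np.ndarray
    ir2: np.ndarray
    ir_combo: np.ndarray

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("dose1", "dose2", "ir1", "ir2", "ir_combo"):
            arrays[name] = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
        lengths = {v.shape[0] for v in arrays.values()}
        if len(lengths) != 1:
            raise ValueError("all columns must have the same number of dose rows")
        if arrays["ir1"].shape[0] == 0:
            raise ValueError("dose-response table is empty")

        rates = np.concatenate([arrays["ir1"], arrays["ir2"], arrays["ir_combo"]])
        if np.nanmax(rates) > 1.0:
            warnings.warn(
                "inhibition rates above 1 detected; interpreting input as "
                "percentages and dividing by 100",
                stacklevel=2,
            )
            for name in ("ir1", "ir2", "ir_combo"):
                arrays[name] = arrays[name] / 100.0
        for name in ("ir1", "ir2", "ir_combo"):
            col = arrays[name]
            if np.any((col < -1e-12) | (col > 1 + 1e-12)):
                raise ValueError(f"{name}: inhibition rates must lie in [0, 1]")
        for name, v in arrays.items():
            object.__setattr__(self, name, v)

        ok = (arrays["dose2"] > 0) & (arrays["dose1"] > 0)
        if ok.sum() >= 2:
            ratios = arrays["dose1"][ok] / arrays["dose2"][ok]
            if np.max(ratios) - np.min(ratios) > 1e-6 * max(np.max(ratios), 1.0):
                warnings.warn(
                    "dose1:dose2 ratio varies across rows; the fixed-ratio "
                    "design assumption does not hold",
                    stacklevel=2,
                )

    def __len__(self) -> int:
        return int(self.ir_combo.shape[0])

    @property
    def ir_additive(self) -> np.ndarray:
        return bliss_additive(self.ir1, self.ir2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dose1": self.dose1,
                "dose2": self.dose2,
                "ir1": self.ir1,
                "ir2": self.ir2,
                "ir_combo": self.ir_combo,
            }
        )


def bliss_additive(ir1, ir2):
    """Bliss additive inhibition IR1 + IR2 − IR1·IR2 (scalar or array)."""
    a = np.asarray(ir1, dtype=float)
    b = np.asarray(ir2, dtype=float)
    if np.any((a < 0) | (a > 1)) or np.any((b < 0) | (b > 1)):
        raise ValueError("inhibition rates must lie in [0, 1]")
    out = a + b - a * b
    if out.ndim == 0:
        return float(out)
    return out


def miir(
    table: DoseResponseTable,
    effective_only: bool = False,
    threshold: float = EFFECTIVE_THRESHOLD,
) -> tuple[float, int]:
    """Maximum Increased Inhibition Rate and the dose row attaining it.

    MIIR = max over rows of (IR_syn − IR_add); negative values indicate a
    sub-additive combination at every dose.  With ``effective_only`` the
    maximum runs only over rows whose combination inhibition exceeds the
    effectiveness threshold.
    """
    if len(table) == 0:
        raise ValueError("dose-response table is empty")
    delta = table.ir_combo - table.ir_additive
    if effective_only:
        mask = effective_combination_filter(table, threshold)
        if not mask.any():
            raise ValueError(
                f"no dose row exceeds the {threshold:.0%} effectiveness threshold"
            )
        candidates = np.where(mask)[0]
    else:
        candidates = np.arange(len(table))
    best = candidates[int(np.argmax(delta[candidates]))]
    return float(delta[best]), int(best)


def effective_combination_filter(
    table: DoseResponseTable, threshold: float = EFFECTIVE_THRESHOLD
) -> np.ndarray:
    """Boolean per dose row: combination inhibition strictly above threshold."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    return table.ir_combo > threshold


def load_dose_response(path: str | Path) -> DoseResponseTable:
    """Load a dose-response TSV with columns dose1, dose2, ir1, ir2, ir_combo."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["dose1", "dose2", "ir1", "ir2", "ir_combo"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return DoseResponseTable(*(df[c].to_numpy() for c in required))
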