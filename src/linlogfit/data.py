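"""Tabular container for titration (dose-response) data."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["DoseResponseTable"]


@dataclass
class DoseResponseTable:
    """One titration experiment: graded doses and a measured response.

    Parameters
    ----------
    dose : array-like
        Dose values (dietary %, g/d, AA:Lys ratio, ...), one per
        observation.  Any consistent unit.
    response : array-like
        Response values (weight gain, N retention, titre, ...) matching
        ``dose`` in length.
    replicate_id : array-like, optional
        Grouping labels for replicate observations at the same dose.
    dose_unit, response_unit : str
        Free-text unit metadata, carried through reports.
    """

    dose: np.ndarray
    response: np.ndarray
    replicate_id: Optional[np.ndarray] = None
    dose_unit: str = ""
    response_unit: str = ""

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float).ravel()
        self.response = np.asarray(self.response, dtype=float).ravel()
        if self.dose.size != self.response.size:
            raise ValueError(
                f"dose ({self.dose.size}) and response ({self.response.size}) "
                "must have equal length"
            )
        if self.dose.size == 0:
            raise ValueError("empty table")
        if not np.all(np.isfinite(self.dose)):
            raise ValueError("non-finite dose values")
        if not np.all(np.isfinite(self.response)):
            raise ValueError("non-finite response values")
        if self.replicate_id is not None:
            self.replicate_id = np.asarray(self.replicate_id).ravel()
            if self.replicate_id.size != self.dose.size:
                raise ValueError("replicate_id length mismatch")

    def __len__(self) -> int:
        return int(self.dose.size)

    @property
    def n_levels(self) -> int:
        return int(np.unique(self.dose).size)

    @property
    def dose_range(self) -> float:
        return float(self.dose.max() - self.dose.min())

    def level_means(self) -> "DoseResponseTable":
        """Collapse replicates to per-dose-level means."""
        levels, inverse = np.unique(self.dose, return_inverse=True)
        means = np.bincount(inverse, weights=self.response) / np.bincount(inverse)
        return DoseResponseTable(
            levels, means, dose_unit=self.dose_unit, response_unit=self.response_unit
        )

    def subset(self, index: Sequence[int]) -> "DoseResponseTable":
        index = np.asarray(index, dtype=int)
        rep = self.replicate_id[index] if self.replicate_id is not None else None
        return DoseResponseTable(
            self.dose[index],
            self.response[index],
            replicate_id=rep,
            dose_unit=self.dose_unit,
            response_unit=self.response_unit,
        )

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"dose": self.dose, "response": self.response})
        if self.replicate_id is not None:
            out["replicate_id"] = self.replicate_id
        return out
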