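"""Core containers for time-course expression data.

An :class:`ExpressionDataset` holds a gene x sample matrix of log2
intensities together with per-sample annotations (strain, sampling time in
hours, replicate).  A :class:`ProfileMatrix` holds one profile per gene in
one of the two clustering views:

``NP``
    normalized profile — each row centred to mean 0 and scaled to sample
    standard deviation 1, emphasising the *shape* of the trajectory.
``FC``
    fold-change profile — per-time log2 ratio of the producer strain over
    the control strain, so -1 means 2-fold down and +1 means 2-fold up in
    the producer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_METADATA = ("strain", "time_h", "replicate")


@dataclass
class ExpressionDataset:
    """Gene x sample log2 expression matrix plus sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene identifier, one column per sample.
    metadata
        DataFrame indexed by sample identifier with columns
        ``strain``, ``time_h`` and ``replicate``; must cover every
        sample column of ``values``.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene identifiers: {list(dupes[:5])}")
        missing_cols = [c for c in REQUIRED_METADATA if c not in self.metadata.columns]
        if missing_cols:
            raise ValueError(f"metadata missing required columns: {missing_cols}")
        uncovered = [s for s in self.values.columns if s not in self.metadata.index]
        if uncovered:
            raise ValueError(f"samples without metadata: {uncovered[:5]}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def strains(self) -> list[str]:
        meta = self.metadata.loc[self.samples]
        return list(dict.fromkeys(meta["strain"]))

    @property
    def times(self) -> list[float]:
        meta = self.metadata.loc[self.samples]
        return sorted(set(meta["time_h"]))

    def group_labels(self) -> pd.Series:
        """Condition label ``{strain}_{time}h`` per sample, for DE designs."""
        meta = self.metadata.loc[self.samples]
        return pd.Series(
            [f"{s}_{_fmt_time(t)}h" for s, t in zip(meta["strain"], meta["time_h"])],
            index=self.samples,
        )


def _fmt_time(t: float) -> str:
    t = float(t)
    return str(int(t)) if t == int(t) else str(t)


@dataclass
class ProfileMatrix:
    """One profile per gene, in the NP or FC view.

    ``values`` columns are time labels (FC) or ``(strain, time)`` pairs
    rendered as ``strain@time`` strings (NP over one or both strains).
    Degenerate genes (zero row variance before NP scaling) are excluded
    from ``values`` and listed in ``degenerate``.
    """

    values: pd.DataFrame
    view: str  # "NP" or "FC"
    times: list[float]
    strain_context: tuple[str, ...]
    degenerate: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.view not in ("NP", "FC"):
            raise ValueError(f"view must be 'NP' or 'FC', got {self.view!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)
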