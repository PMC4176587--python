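"""Construction of the two clustering input views and the qPCR transform.

From a replicate-level :class:`~tempoclust.dataset.ExpressionDataset` this
module builds

* **NP** (normalized profiles): replicate-averaged trajectories scaled and
  centred per gene to mean 0, standard deviation 1, so clustering sees the
  shape of the response rather than its magnitude.  By default the
  producer and control trajectories are concatenated into one profile per
  gene before scaling, so both strains' shapes live in a single vector;
  per-strain scaling is available via ``per_strain=True``.
* **FC** (fold-change profiles): per-time log2 ratio of producer over
  control replicate means; -1 means 2-fold down, +1 means 2-fold up in
  the producer.

Genes are not filtered before clustering; only mathematically degenerate
rows (zero variance, for which the NP scaling is undefined) are excluded,
and those are reported, not silently dropped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset, ProfileMatrix


def average_replicates(ds: ExpressionDataset) -> pd.DataFrame:
    """Arithmetic mean over replicates per (strain, time) condition.

    Returns a gene x condition DataFrame whose columns are a MultiIndex
    ``(strain, time_h)``.  Raises if any (strain, time) cell has no
    replicate.
    """
    meta = ds.metadata.loc[ds.samples]
    strains = list(dict.fromkeys(meta["strain"]))
    times = sorted(set(meta["time_h"]))
    blocks = {}
    for strain in strains:
        for time in times:
            cols = meta.index[(meta["strain"] == strain) & (meta["time_h"] == time)]
            if len(cols) == 0:
                raise ValueError(f"no replicates for (strain={strain!r}, time={time})")
            blocks[(strain, time)] = ds.values[list(cols)].mean(axis=1)
    out = pd.DataFrame(blocks)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["strain", "time_h"])
    return out


def normalized_profiles(
    mat: pd.DataFrame,
    strain: str | list[str] | None = None,
    per_strain: bool = False,
) -> ProfileMatrix:
    """Scale each gene's profile to mean 0, standard deviation 1 (ddof=1).

    ``mat`` is the replicate-averaged matrix from :func:`average_replicates`.
    ``strain=None`` uses all strains, concatenated into one profile per
    gene (the default clustering input); a single strain name restricts to
    that strain.  With ``per_strain=True`` each strain's segment is scaled
    separately before concatenation.

    Zero-variance rows are flagged degenerate: excluded from the returned
    values but listed in ``ProfileMatrix.degenerate``.
    """
    strains = list(mat.columns.get_level_values("strain").unique())
    if strain is not None:
        wanted = [strain] if isinstance(strain, str) else list(strain)
        missing = [s for s in wanted if s not in strains]
        if missing:
            raise ValueError(f"strain(s) not present: {missing}")
        strains = wanted
    times = sorted(set(mat.columns.get_level_values("time_h")))
    if len(times) < 2:
        raise ValueError("need at least 2 time points for normalized profiles")

    segments = [mat[s][times] for s in strains]  # gene x time per strain

    def zscore(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
        mu = df.mean(axis=1)
        sd = df.std(axis=1, ddof=1)
        return df.sub(mu, axis=0).div(sd, axis=0), sd

    if per_strain:
        scaled, sds = zip(*(zscore(seg) for seg in segments))
        degenerate_mask = pd.concat(sds, axis=1).min(axis=1) == 0
        wide = pd.concat(scaled, axis=1)
    else:
        wide = pd.concat(segments, axis=1)
        wide, sd = zscore(wide)
        degenerate_mask = sd == 0

    wide.columns = [f"{s}@{t}" for s in strains for t in times]
    degenerate = list(wide.index[degenerate_mask])
    values = wide.loc[~degenerate_mask]
    return ProfileMatrix(
        values=values, view="NP", times=list(times),
        strain_context=tuple(strains), degenerate=degenerate,
    )


def fold_change_profiles(
    mat: pd.DataFrame, producer_strain: str, control_strain: str
) -> ProfileMatrix:
    """Per-gene, per-time log2 ratio producer - control (inputs are log2)."""
    for s in (producer_strain, control_strain):
        if s not in mat.columns.get_level_values("strain"):
            raise ValueError(f"strain not present: {s!r}")
    prod = mat[producer_strain]
    ctrl = mat[control_strain]
    if list(prod.columns) != list(ctrl.columns):
        raise ValueError(
            f"time grids differ between strains: {list(prod.columns)} vs {list(ctrl.columns)}"
        )
    fc = prod - ctrl
    fc.columns = [f"{t}" for t in prod.columns]
    return ProfileMatrix(
        values=fc, view="FC", times=list(prod.columns),
        strain_context=(producer_strain, control_strain),
    )


def relative_expression_from_ct(ct_values) -> np.ndarray:
    """qPCR relative abundance from C_t, as percent of the maximum.

    Abundance is 2^(-C_t) (one doubling per cycle, no efficiency
    correction); the output is 100 * abundance / max(abundance), so the
    condition with the lowest C_t reads exactly 100.
    """
    ct = np.asarray(ct_values, dtype=float)
    if ct.size == 0:
        raise ValueError("need at least one C_t value")
    if not np.isfinite(ct).all():
        raise ValueError("C_t values must be finite")
    # shift by the minimum before exponentiating to avoid underflow
    rel = np.exp2(-(ct - ct.min()))
    return 100.0 * rel / rel.max()
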