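"""Per-gene linear models with empirical-Bayes variance moderation.

Every comparison here is a pair of experimental conditions (one-way
group-means layout): per gene, group means are replicate means, the
residual variance ``s2_g`` is pooled across groups with ``d_g = n -
n_levels`` degrees of freedom, and the per-gene variances are shrunk
toward a common prior ``s0^2`` with prior degrees of freedom ``d0``
estimated from the ensemble of genes by moment matching on ``log s2``
(digamma/trigamma identities).  The moderated t for contrast A - B is

    t_g = (mean_A - mean_B) / (s_tilde_g * sqrt(1/n_A + 1/n_B)),
    s_tilde_g^2 = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g),

with two-sided p-values on d0 + d_g degrees of freedom, and
Benjamini-Hochberg adjustment across genes per contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .dataset import ExpressionDataset


@dataclass
class DesignSpec:
    """Sample-to-group assignment and the contrasts to test.

    ``groups`` maps each sample id to a factor level such as
    ``producer_47h``; each contrast is a pair ``(level_A, level_B)``
    tested as A - B.
    """

    samples: list[str]
    groups: list[str]
    contrasts: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.groups):
            raise ValueError("samples and groups must have equal length")
        counts = pd.Series(self.groups).value_counts()
        for a, b in self.contrasts:
            for lvl in (a, b):
                if lvl not in counts.index:
                    raise ValueError(f"contrast references unknown level {lvl!r}")
                if counts[lvl] < 2:
                    raise ValueError(
                        f"level {lvl!r} has {counts[lvl]} sample(s); need >= 2 "
                        "for variance estimation"
                    )

    @classmethod
    def paired_timepoints(cls, ds: ExpressionDataset,
                          producer: str, control: str) -> "DesignSpec":
        """Producer-vs-control contrast at every shared time point."""
        labels = ds.group_labels()
        times = ds.times
        contrasts = []
        for t in times:
            t_str = str(int(t)) if float(t) == int(t) else str(t)
            contrasts.append((f"{producer}_{t_str}h", f"{control}_{t_str}h"))
        return cls(samples=list(labels.index), groups=list(labels), contrasts=contrasts)


@dataclass
class FitResult:
    group_means: pd.DataFrame  # gene x level
    s2: pd.Series              # pooled residual variance per gene
    df_residual: float
    n_per_level: dict[str, int]
    contrasts: list[tuple[str, str]]


@dataclass
class DEResult:
    """Per-gene, per-contrast moderated differential expression."""

    table: pd.DataFrame  # columns: gene, contrast, log2fc, t_mod, p_raw, p_adj
    d0: float
    s0_sq: float
    df_residual: float
    s2: pd.Series = field(repr=False, default=None)


def fit_models(ds: ExpressionDataset, design: DesignSpec) -> FitResult:
    """Least-squares fit of the one-way group-means model per gene."""
    missing = [s for s in design.samples if s not in ds.values.columns]
    if missing:
        raise ValueError(f"designed samples absent from dataset: {missing[:5]}")
    X = ds.values[design.samples]
    groups = pd.Series(design.groups, index=design.samples)
    levels = list(dict.fromkeys(design.groups))
    df_residual = len(design.samples) - len(levels)
    if df_residual <= 0:
        raise ValueError(
            f"no residual degrees of freedom: {len(design.samples)} samples, "
            f"{len(levels)} levels"
        )
    means = {}
    rss = np.zeros(len(X))
    n_per_level = {}
    for lvl in levels:
        cols = list(groups.index[groups == lvl])
        n_per_level[lvl] = len(cols)
        block = X[cols]
        mu = block.mean(axis=1)
        means[lvl] = mu
        rss += ((block.sub(mu, axis=0)) ** 2).sum(axis=1).to_numpy()
    s2 = pd.Series(rss / df_residual, index=X.index, name="s2")
    return FitResult(pd.DataFrame(means), s2, float(df_residual), n_per_level,
                     list(design.contrasts))


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    trigamma is strictly decreasing on (0, inf) with range (0, inf); the
    starting point 0.5 + 1/y is accurate at both extremes.
    """
    if y <= 0:
        raise ValueError("trigamma_inverse requires y > 0")
    if y > 1e7:  # trigamma(x) ~ 1/x^2 as x -> 0
        return 1.0 / np.sqrt(y)
    if y < 1e-6:  # trigamma(x) ~ 1/x as x -> inf
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: float, d0_cap: float = 1e6) -> tuple[float, float]:
    """Estimate prior df d0 and prior variance s0^2 from per-gene variances.

    Under the hierarchical model ``s2_g ~ s0^2 * chi2_df / df`` scaled by a
    gene variance drawn from a scaled inverse-chi-square with d0 degrees
    of freedom, ``log s2_g`` has a shifted log-F distribution whose first
    two moments involve digamma/trigamma functions; matching them gives
    closed-form estimates, with one Newton-solved trigamma inversion.
    d0 above ``d0_cap`` is reported as +inf (variances underdispersed
    relative to pure chi-square sampling noise).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 10:
        raise ValueError("need >= 10 genes with positive residual variance")
    if np.allclose(s2, 0):
        raise ValueError("all residual variances are zero: degenerate ensemble")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        if d0 > d0_cap:
            d0 = np.inf
    else:
        d0 = np.inf
    if np.isinf(d0):
        s0_sq = float(np.exp(emean))
    else:
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0_sq


def moderate(
    fits: FitResult,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> DEResult:
    """Moderated t-statistics and two-sided p-values for each contrast.

    ``prior_df``/``prior_var`` override the estimated hyperparameters
    (``prior_df=0`` recovers the ordinary pooled two-sample t;
    ``prior_df=inf`` uses the prior variance for every gene).
    """
    s2 = fits.s2.to_numpy()
    df = fits.df_residual
    if prior_df is None or prior_var is None:
        d0_est, s0_est = estimate_prior(s2, df)
        d0 = d0_est if prior_df is None else float(prior_df)
        s0_sq = s0_est if prior_var is None else float(prior_var)
    else:
        d0, s0_sq = float(prior_df), float(prior_var)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = df
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df

    rows = []
    genes = fits.group_means.index
    for a, b in fits.contrasts:
        lfc = (fits.group_means[a] - fits.group_means[b]).to_numpy()
        se = np.sqrt(s2_post * (1.0 / fits.n_per_level[a] + 1.0 / fits.n_per_level[b]))
        with np.errstate(divide="ignore", invalid="ignore"):
            t_mod = lfc / se
        t_mod = np.where(np.isnan(t_mod), 0.0, t_mod)  # 0/0: no change, no evidence
        if np.isinf(df_total):
            p_raw = 2.0 * stats.norm.sf(np.abs(t_mod))
        else:
            p_raw = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
        p_adj = adjust_bh(p_raw)
        rows.append(pd.DataFrame({
            "gene": genes, "contrast": f"{a}:{b}", "log2fc": lfc,
            "t_mod": t_mod, "p_raw": p_raw, "p_adj": p_adj,
        }))
    table = pd.concat(rows, ignore_index=True)
    return DEResult(table=table, d0=d0, s0_sq=s0_sq, df_residual=df, s2=fits.s2)


def adjust_bh(p_raw) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_significant(
    de: DEResult,
    p_cut: float = 1e-5,
    lfc_cut: float = 1.0,
    use_adjusted: bool = True,
) -> dict[str, set[str]]:
    """Genes with adjusted p below ``p_cut`` and |log2fc| >= ``lfc_cut``,
    per contrast.  ``use_adjusted=False`` applies the p cut-off to raw p."""
    pcol = "p_adj" if use_adjusted else "p_raw"
    t = de.table
    mask = (t[pcol] < p_cut) & (t["log2fc"].abs() >= lfc_cut)
    out: dict[str, set[str]] = {c: set() for c in t["contrast"].unique()}
    for contrast, sub in t[mask].groupby("contrast"):
        out[contrast] = set(sub["gene"])
    return out
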