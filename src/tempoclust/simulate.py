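"""Synthetic two-strain time-course expression data with planted structure.

Generates every input the analysis pipeline consumes, with ground truth
returned alongside: a gene x sample log2 matrix drawn from temporal
archetypes (steady up, steady down, transient, delayed, flat-but-induced),
annotation term sets enriched in chosen archetypes, and a panel of
pseudo-studies sharing partially overlapping response modules for the
cross-study integration stage.

The default design mirrors a two-strain bioreactor experiment: a producer
and a control strain, six sampling times, three independent cultures per
strain, additive Gaussian replicate noise on the log2 scale.  Ground truth
is always returned separately from the dataset, never embedded in gene
identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .enrichment import TermMap
from .integrate import StudyComparison

DEFAULT_TIMES = (0.0, 7.0, 23.0, 47.0, 49.0, 71.0)
DEFAULT_STRAINS = ("producer", "control")
DEFAULT_NOISE_SD = 0.2  # log2 units per replicate measurement


@dataclass
class ArchetypeSpec:
    """A planted temporal expression archetype.

    ``base_profile`` gives the per-time-point log2 mean for the control
    strain; ``strain_effect`` is an additive per-time-point offset applied
    to the producer strain only, so it is also the planted log2
    fold-change profile of that archetype.
    """

    name: str
    base_profile: np.ndarray
    n_genes: int
    noise_sd: float = DEFAULT_NOISE_SD
    strain_effect: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.base_profile = np.asarray(self.base_profile, dtype=float)
        if self.strain_effect is None:
            self.strain_effect = np.zeros_like(self.base_profile)
        self.strain_effect = np.asarray(self.strain_effect, dtype=float)
        if self.n_genes < 1:
            raise ValueError(f"archetype {self.name!r}: n_genes must be >= 1")
        if self.noise_sd < 0:
            raise ValueError(f"archetype {self.name!r}: noise_sd must be >= 0")
        if self.strain_effect.shape != self.base_profile.shape:
            raise ValueError(
                f"archetype {self.name!r}: strain_effect length "
                f"{len(self.strain_effect)} != base_profile length {len(self.base_profile)}"
            )


@dataclass
class TermSpec:
    """Recipe for one planted annotation term."""

    term_id: str
    archetype: str | None  # None -> background-only term
    n_in_term: int
    n_background: int


@dataclass
class SimulationConfig:
    archetypes: list[ArchetypeSpec]
    seed: int
    times: tuple[float, ...] = DEFAULT_TIMES
    n_replicates: int = 3
    strains: tuple[str, str] = DEFAULT_STRAINS
    term_config: list[TermSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_timepoints(self) -> int:
        return len(self.times)

    @property
    def n_genes(self) -> int:
        return sum(a.n_genes for a in self.archetypes)

    def validate(self) -> None:
        if not self.archetypes:
            raise ValueError("at least one archetype is required")
        if self.n_timepoints < 2:
            raise ValueError("need at least 2 time points")
        if self.n_replicates < 1:
            raise ValueError("need at least 1 replicate")
        if len(self.strains) != 2:
            raise ValueError("exactly two strains (producer, control) expected")
        names = {a.name for a in self.archetypes}
        if len(names) != len(self.archetypes):
            raise ValueError("archetype names must be unique")
        for a in self.archetypes:
            if len(a.base_profile) != self.n_timepoints:
                raise ValueError(
                    f"archetype {a.name!r}: base_profile length {len(a.base_profile)} "
                    f"!= number of time points {self.n_timepoints}"
                )
        by_name = {a.name: a for a in self.archetypes}
        for t in self.term_config:
            if t.archetype is not None and t.archetype not in names:
                raise ValueError(f"term {t.term_id!r} references unknown archetype {t.archetype!r}")
            if t.archetype is not None and t.n_in_term > by_name[t.archetype].n_genes:
                raise ValueError(
                    f"term {t.term_id!r}: n_in_term {t.n_in_term} exceeds archetype size "
                    f"{by_name[t.archetype].n_genes}"
                )


def default_archetypes(
    n_genes_per_archetype: int = 200, noise_sd: float = DEFAULT_NOISE_SD
) -> list[ArchetypeSpec]:
    """The five stock archetypes: steady up / steady down / transient /
    delayed induction / temporally flat but producer-induced.

    Amplitudes span 2-3 log2 units (4- to 8-fold), typical of strongly
    responding genes, and the shapes are mutually distinguishable in both
    the NP view (trajectory shape, both strains concatenated) and the FC
    view (producer-vs-control ratio).
    """
    n = n_genes_per_archetype
    return [
        ArchetypeSpec(
            "steady_up", [0.0, 1.0, 2.0, 2.6, 2.8, 3.0], n, noise_sd,
            strain_effect=[0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        ),
        ArchetypeSpec(
            "steady_down", [0.0, -1.0, -2.0, -2.6, -2.8, -3.0], n, noise_sd,
            strain_effect=[0.0, -0.5, -1.0, -1.5, -1.5, -1.5],
        ),
        ArchetypeSpec(
            "transient", [0.0, 2.8, 1.2, 0.3, 0.2, 0.0], n, noise_sd,
            strain_effect=[0.0, 1.0, 1.0, 1.0, 1.0, 1.0],
        ),
        ArchetypeSpec(
            "delayed", [0.0, 0.0, 0.0, 0.3, 1.8, 3.0], n, noise_sd,
            strain_effect=[0.0, 0.0, 0.0, 0.5, 1.5, 2.0],
        ),
        ArchetypeSpec(
            "flat_induced", [0.0, 0.0, 0.0, 0.0, 0.0, 0.0], n, noise_sd,
            strain_effect=[0.0, 1.0, 2.0, 2.5, 2.5, 2.5],
        ),
    ]


def default_config(seed: int, n_genes_per_archetype: int = 200,
                   noise_sd: float = DEFAULT_NOISE_SD) -> SimulationConfig:
    archetypes = default_archetypes(n_genes_per_archetype, noise_sd)
    terms = [
        TermSpec("TERM:UP", "steady_up", min(50, n_genes_per_archetype), 0),
        TermSpec("TERM:DOWN", "steady_down", min(50, n_genes_per_archetype), 5),
        TermSpec("TERM:TRANSIENT", "transient", min(40, n_genes_per_archetype), 10),
        TermSpec("TERM:BACKGROUND", None, 0, 30),
    ]
    return SimulationConfig(archetypes=archetypes, seed=seed, term_config=terms)


def _sample_id(strain: str, time: float, rep: int) -> str:
    t = int(time) if float(time) == int(time) else time
    return f"{strain}_t{t}_r{rep}"


def simulate_timecourse(config: SimulationConfig) -> tuple[ExpressionDataset, pd.Series]:
    """Draw the gene x sample matrix and return it with the ground truth.

    Every value is archetype mean (+ strain_effect for the producer
    strain) + Gaussian(0, noise_sd) on the log2 scale.  Returns the
    dataset and a Series mapping gene id -> archetype name.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    producer, control = config.strains
    T, R = config.n_timepoints, config.n_replicates

    sample_ids, meta_rows = [], []
    for strain in config.strains:
        for time in config.times:
            for rep in range(1, R + 1):
                sample_ids.append(_sample_id(strain, time, rep))
                meta_rows.append({"strain": strain, "time_h": float(time), "replicate": rep})
    metadata = pd.DataFrame(meta_rows, index=sample_ids)

    n_genes = config.n_genes
    genes = [f"g{i:05d}" for i in range(1, n_genes + 1)]
    values = np.empty((n_genes, len(sample_ids)))
    truth = []
    row = 0
    for arch in config.archetypes:
        means = {
            producer: arch.base_profile + arch.strain_effect,
            control: arch.base_profile,
        }
        block = np.empty((arch.n_genes, len(sample_ids)))
        col = 0
        for strain in config.strains:
            for ti in range(T):
                mu = means[strain][ti]
                block[:, col:col + R] = mu + rng.normal(0.0, arch.noise_sd, size=(arch.n_genes, R))
                col += R
        values[row:row + arch.n_genes] = block
        truth.extend([arch.name] * arch.n_genes)
        row += arch.n_genes

    ds = ExpressionDataset(pd.DataFrame(values, index=genes, columns=sample_ids), metadata)
    return ds, pd.Series(truth, index=genes, name="archetype")


def simulate_term_map(config: SimulationConfig, truth: pd.Series) -> TermMap:
    """Build annotation term sets per the config's term recipes.

    Each term draws ``n_in_term`` member genes from its source archetype
    and ``n_background`` genes from the remaining archetypes, without
    replacement within a term.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    universe = list(truth.index)
    terms: dict[str, set[str]] = {}
    for spec in config.term_config:
        if spec.archetype is not None:
            pool = list(truth.index[truth == spec.archetype])
            if spec.n_in_term > len(pool):
                raise ValueError(
                    f"term {spec.term_id!r}: n_in_term {spec.n_in_term} exceeds "
                    f"archetype size {len(pool)}"
                )
            members = list(rng.choice(pool, size=spec.n_in_term, replace=False))
            background_pool = list(truth.index[truth != spec.archetype])
        else:
            members = []
            background_pool = universe
        if spec.n_background > 0:
            members += list(rng.choice(background_pool, size=spec.n_background, replace=False))
        terms[spec.term_id] = set(members)
    return TermMap(terms=terms, universe=set(universe))


@dataclass
class StudyModule:
    """A planted cross-study response module: a gene set perturbed by a
    common log2 effect in a subset of studies."""

    genes: list[str]
    studies: list[int]  # 0-based study indices
    effect: float


def simulate_multistudy(
    n_studies: int,
    n_genes: int,
    modules: list[StudyModule],
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    truth_threshold: float = 1.0,
) -> tuple[list[StudyComparison], pd.DataFrame]:
    """Simulate a panel of study comparisons for meta-integration.

    Each study column holds per-gene log2 ratios (case vs its own control):
    module effects for affected gene sets plus Gaussian noise.  The
    significance flag is set where ``|log2 ratio| > truth_threshold``.
    Returns the studies and the ground-truth effect matrix (gene x study).
    """
    if n_studies < 1 or n_genes < 1:
        raise ValueError("n_studies and n_genes must be >= 1")
    genes = [f"g{i:05d}" for i in range(1, n_genes + 1)]
    gene_set = set(genes)
    effects = pd.DataFrame(0.0, index=genes, columns=range(n_studies))
    claimed: dict[tuple[str, int], float] = {}
    for mod in modules:
        unknown = set(mod.genes) - gene_set
        if unknown:
            raise ValueError(f"module genes outside universe: {sorted(unknown)[:5]}")
        bad = [s for s in mod.studies if not (0 <= s < n_studies)]
        if bad:
            raise ValueError(f"module study indices out of range: {bad}")
        for g in mod.genes:
            for s in mod.studies:
                prev = claimed.get((g, s))
                if prev is not None and prev != mod.effect:
                    raise ValueError(
                        f"conflicting effects for gene {g!r} in study {s}: {prev} vs {mod.effect}"
                    )
                claimed[(g, s)] = mod.effect
                effects.loc[g, s] = mod.effect

    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    studies = []
    for s in range(n_studies):
        ratios = pd.Series(
            effects[s].to_numpy() + rng.normal(0.0, noise_sd, size=n_genes),
            index=genes, name=f"study{s:02d}",
        )
        significant = ratios.abs() > truth_threshold
        studies.append(
            StudyComparison(
                study_id=f"study{s:02d}", ratios=ratios, significant=significant,
                note="synthetic pseudo-study",
            )
        )
    return studies, effects


def permute_matrix(X, seed: int = 0):
    """Row-wise independent permutation — the 'randomized data set'.

    Each row's values are permuted independently across columns, which
    preserves every per-gene value multiset while destroying temporal and
    cross-gene structure.  Accepts a DataFrame, ProfileMatrix values, or
    ndarray; returns the same type (DataFrame keeps its labels).
    """
    is_df = isinstance(X, pd.DataFrame)
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if not np.isfinite(arr).all():
        raise ValueError("permute_matrix requires finite input")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    out = rng.permuted(arr, axis=1)
    if is_df:
        return pd.DataFrame(out, index=X.index, columns=X.columns)
    return out if np.asarray(X).ndim > 1 else out[0]
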