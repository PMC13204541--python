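"""Synthetic cohorts of connectomes and diffusivity records.

The generator emulates the statistical structure the downstream
analysis assumes: per-edge streamline counts that are right-skewed and
zero-inflated, with optional planted multiplicative group effects on
chosen edges, and per-region tensor eigenvalues with optional planted
mean shifts on chosen diffusivity scalars.

Count model: each edge of a cohort carries a structural-zero mask drawn
once (probability ``zero_prob``, shared across animals and groups);
unmasked edges draw ``round(lognormal(baseline_log_mean,
baseline_log_sd))`` per animal.  For KO animals, edges named in
``planted_edges`` have the lognormal mean multiplied by the stated
effect.  Because the noise is Gaussian on the log scale, the log(x+1)
pooled t-test downstream operates under essentially its own model
assumptions, which makes type-I-error behaviour cleanly checkable.

All randomness flows from one integer seed through a spawned
seed-sequence tree (mask, per-animal counts, diffusivity), so identical
configs produce bit-identical cohorts regardless of iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .connectome import Connectome
from .diffusivity import DiffusivityRecord
from .parcellation import RegionTable, default_region_table, generic_region_table

__all__ = [
    "PlantedEdge",
    "PlantedRegion",
    "SimulationConfig",
    "CohortStudy",
    "simulate_cohort",
    "simulate_diffusivity",
    "bilateral_planted_edges",
]

#: Default per-region eigenvalue baselines, mm^2/s — typical mouse
#: gray/white matter scale (moderately anisotropic tensor).
DEFAULT_EIGEN_BASELINE = (1.2e-3, 0.7e-3, 0.5e-3)


@dataclass(frozen=True)
class PlantedEdge:
    """A region pair whose KO lognormal mean is multiplied by ``effect``."""

    region_a: int
    region_b: int
    effect: float

    def __post_init__(self) -> None:
        if self.region_a == self.region_b:
            raise ValueError("planted edge endpoints must differ")
        if self.effect <= 0:
            raise ValueError("planted effect must be > 0")

    @property
    def key(self) -> tuple[int, int]:
        return (min(self.region_a, self.region_b), max(self.region_a, self.region_b))


@dataclass(frozen=True)
class PlantedRegion:
    """A region whose KO eigenvalues are scaled to shift one scalar.

    ``scalar`` in {AD, RD, MD}: AD scales lambda1, RD scales
    lambda2 and lambda3, MD scales all three.
    """

    region_id: int
    scalar: str
    effect: float

    def __post_init__(self) -> None:
        if self.scalar not in ("AD", "RD", "MD"):
            raise ValueError("planted scalar must be one of AD, RD, MD")
        if self.effect <= 0:
            raise ValueError("planted effect must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the study design: 8 wild-type vs 12 knockout
    animals over a 72-region bilateral parcellation.
    """

    n_wt: int = 8
    n_ko: int = 12
    n_regions: int = 72
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 0.5
    zero_prob: float = 0.3
    planted_edges: tuple[PlantedEdge, ...] = ()
    planted_regions: tuple[PlantedRegion, ...] = ()
    diffusivity_log_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_wt < 1 or self.n_ko < 1:
            raise ValueError("group sizes must be positive")
        if self.n_regions % 2 or self.n_regions < 2:
            raise ValueError("n_regions must be even and >= 2")
        if not 0 <= self.zero_prob < 1:
            raise ValueError("zero_prob must lie in [0, 1)")
        if self.baseline_log_sd <= 0:
            raise ValueError("baseline_log_sd must be positive")
        object.__setattr__(self, "planted_edges",
                           tuple(e if isinstance(e, PlantedEdge) else PlantedEdge(*e)
                                 for e in self.planted_edges))
        object.__setattr__(self, "planted_regions",
                           tuple(r if isinstance(r, PlantedRegion) else PlantedRegion(*r)
                                 for r in self.planted_regions))
        keys = [e.key for e in self.planted_edges]
        if len(set(keys)) != len(keys):
            raise ValueError("planted edges must be distinct unordered pairs")
        for e in self.planted_edges:
            if not (0 <= e.key[0] < e.key[1] < self.n_regions):
                raise ValueError(f"planted edge {e.key} outside region range")
        for r in self.planted_regions:
            if not 0 <= r.region_id < self.n_regions:
                raise ValueError(f"planted region {r.region_id} outside region range")


@dataclass
class CohortStudy:
    """A simulated two-group cohort: connectomes, diffusivity, config echo."""

    connectomes: list[Connectome]
    diffusivity: list[DiffusivityRecord]
    config: SimulationConfig
    table: RegionTable = None

    @property
    def groups(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.connectomes:
            out[c.group] = out.get(c.group, 0) + 1
        return out


def bilateral_planted_edges(stem_pairs: Sequence[tuple[int, int]], effect: float,
                            n_regions: int = 72) -> tuple[PlantedEdge, ...]:
    """Plant one effect on both hemispheres' copies of each stem pair.

    ``stem_pairs`` index the per-hemisphere parcellation (0..n/2-1); each
    pair is planted on the left block (i, j) and the right block
    (i + n/2, j + n/2), mirroring a bilateral group difference.
    """
    half = n_regions // 2
    out = []
    for i, j in stem_pairs:
        if not 0 <= i < half and 0 <= j < half:
            raise ValueError(f"stem pair ({i}, {j}) outside 0..{half - 1}")
        out.append(PlantedEdge(i, j, effect))
        out.append(PlantedEdge(i + half, j + half, effect))
    return tuple(out)


def _table_for(config: SimulationConfig) -> RegionTable:
    if config.n_regions == 72:
        return default_region_table()
    return generic_region_table(config.n_regions)


def simulate_cohort(config: SimulationConfig,
                    table: RegionTable | None = None,
                    with_diffusivity: bool = True) -> CohortStudy:
    """Draw one cohort under the configured study conditions.

    Identical config (including seed) yields a bit-identical cohort.
    """
    if table is None:
        table = _table_for(config)
    if table.n_regions != config.n_regions:
        raise ValueError("region table size does not match config.n_regions")
    n = config.n_regions
    root = np.random.SeedSequence(config.seed)
    ss_mask, ss_animals, ss_diff = root.spawn(3)

    iu, ju = np.triu_indices(n, k=1)
    mask_rng = np.random.default_rng(ss_mask)
    structural = mask_rng.random(iu.size) >= config.zero_prob  # True = connected

    log_effect = np.zeros(iu.size)
    if config.planted_edges:
        pos = {(int(a), int(b)): idx for idx, (a, b) in enumerate(zip(iu, ju))}
        for e in config.planted_edges:
            log_effect[pos[e.key]] = np.log(e.effect)

    groups = ["WT"] * config.n_wt + ["KO"] * config.n_ko
    ids = [f"WT{i + 1:02d}" for i in range(config.n_wt)] + \
          [f"KO{i + 1:02d}" for i in range(config.n_ko)]
    animal_seeds = ss_animals.spawn(len(groups))

    connectomes = []
    for animal_id, group, seedseq in zip(ids, groups, animal_seeds):
        rng = np.random.default_rng(seedseq)
        mu = config.baseline_log_mean + (log_effect if group == "KO" else 0.0)
        z = rng.normal(mu, config.baseline_log_sd, size=iu.size)
        counts_u = np.round(np.exp(z)) * structural
        m = np.zeros((n, n))
        m[iu, ju] = counts_u
        m += m.T
        connectomes.append(Connectome(animal_id=animal_id, group=group,
                                      counts=m, labels=table.abbreviations,
                                      table=table))

    records: list[DiffusivityRecord] = []
    if with_diffusivity:
        records = _diffusivity_records(config, ids, groups, ss_diff)
    return CohortStudy(connectomes=connectomes, diffusivity=records,
                       config=config, table=table)


def _diffusivity_records(config, ids, groups, seedseq, eigen_baseline=None) -> list:
    n = config.n_regions
    base = np.array(DEFAULT_EIGEN_BASELINE if eigen_baseline is None else eigen_baseline)
    scale_map = {"AD": np.array([1.0, 0.0, 0.0]),
                 "RD": np.array([0.0, 1.0, 1.0]),
                 "MD": np.array([1.0, 1.0, 1.0])}
    ko_scale = np.ones((n, 3))
    for pr in config.planted_regions:
        sel = scale_map[pr.scalar]
        ko_scale[pr.region_id] *= np.where(sel > 0, pr.effect, 1.0)

    records = []
    animal_seeds = seedseq.spawn(len(ids))
    for animal_id, group, ss in zip(ids, groups, animal_seeds):
        rng = np.random.default_rng(ss)
        noise = np.exp(rng.normal(0.0, config.diffusivity_log_sd, size=(n, 3)))
        lam = base * noise
        if group == "KO":
            lam = lam * ko_scale
        lam = np.sort(lam, axis=1)[:, ::-1]  # enforce lambda1 >= lambda2 >= lambda3
        for region_id in range(n):
            records.append(DiffusivityRecord(
                animal_id=animal_id, group=group, region_id=region_id,
                lambda1=float(lam[region_id, 0]),
                lambda2=float(lam[region_id, 1]),
                lambda3=float(lam[region_id, 2]),
            ))
    return records


def simulate_diffusivity(config: SimulationConfig,
                         eigen_baseline=None) -> list[DiffusivityRecord]:
    """Diffusivity records only, drawn from the same seed tree as the cohort.

    ``eigen_baseline`` overrides the default eigenvalue triple (e.g. an
    isotropic baseline for testing the FA floor).
    """
    root = np.random.SeedSequence(config.seed)
    _, _, ss_diff = root.spawn(3)
    groups = ["WT"] * config.n_wt + ["KO"] * config.n_ko
    ids = [f"WT{i + 1:02d}" for i in range(config.n_wt)] + \
          [f"KO{i + 1:02d}" for i in range(config.n_ko)]
    return _diffusivity_records(config, ids, groups, ss_diff, eigen_baseline)
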