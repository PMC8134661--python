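"""Simulation of correlated bivariate traits on partially overlapping cohorts.

A single biallelic variant G is drawn per individual as Binomial(2, MAF)
under Hardy-Weinberg equilibrium. Traits follow the linear additive model

    Y_k = beta_k * G + eps_k,     k = 1, 2,

with (eps_1, eps_2) bivariate normal, mean 0, Var(eps_k) = 1 - h2_k and
residual correlation rho, so each trait has unit total variance and the
variant explains exactly h2_k of it: beta_k = sqrt(h2_k / (2 MAF (1-MAF))).

The union cohort has three blocks — overlap, cohort-1-only, cohort-2-only —
matching the partial-overlap reality of consortium GWAS (the covariate
trait's scan is typically larger than the adjusted scan). Y1 is generated
for every individual, because the adjusted model regresses Y2 on Y1 on all
of cohort 2, including its non-overlapping part.

Defaults (MAF 0.3, 1,000 replicates) are the benchmark study conditions;
the nested special case n_overlap = n2 < n1 is the headline design.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "ScenarioConfig",
    "StudyReplicate",
    "simulate_genotypes",
    "effect_from_h2",
    "simulate_replicate",
    "scenario_grid",
]

_SEED_MOD = 2**31 - 1


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of one simulation scenario.

    ``h2_1``/``h2_2`` are the fractions of trait variance explained by the
    variant; ``direction`` negates beta_2 when ``"opposite"``; ``rho`` is
    the residual correlation; ``n_overlap`` individuals belong to both
    cohorts (``n_overlap == n2`` nests cohort 2 inside cohort 1).
    """

    h2_1: float
    h2_2: float
    rho: float
    n1: int
    n2: int
    n_overlap: int
    maf: float = 0.3
    direction: Literal["same", "opposite"] = "same"
    reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.maf <= 0.5:
            raise ValueError(f"maf must be in (0, 0.5], got {self.maf}")
        for name in ("h2_1", "h2_2"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if not -1 < self.rho < 1:
            raise ValueError(f"rho must be in (-1, 1), got {self.rho}")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("cohort sizes must be positive")
        if not 0 <= self.n_overlap <= min(self.n1, self.n2):
            raise ValueError(
                f"n_overlap must be in [0, min(n1, n2)], got {self.n_overlap}"
            )
        if self.direction not in ("same", "opposite"):
            raise ValueError(f"direction must be 'same' or 'opposite', got {self.direction!r}")
        if self.reps < 1:
            raise ValueError(f"reps must be >= 1, got {self.reps}")

    @property
    def is_null(self) -> bool:
        return self.h2_1 == 0 and self.h2_2 == 0

    @property
    def n_union(self) -> int:
        return self.n1 + self.n2 - self.n_overlap


@dataclass
class StudyReplicate:
    """One simulated dataset over the union cohort.

    Union ordering is [overlap, only-1, only-2]; cohort 1 is the first
    ``n1`` individuals, cohort 2 is the overlap block plus the trailing
    only-2 block. ``y1_all`` exists on the full union so the adjusted model
    can use Y1 as a covariate everywhere in cohort 2.
    """

    g: np.ndarray
    y1_all: np.ndarray
    y2_all: np.ndarray
    membership: np.ndarray
    n1: int
    n2: int
    n_overlap: int

    @property
    def _cohort2_idx(self) -> np.ndarray:
        n_union = self.n1 + self.n2 - self.n_overlap
        return np.r_[0 : self.n_overlap, self.n1 : n_union]

    @property
    def y1(self) -> np.ndarray:
        """Covariate trait on its own (cohort 1) sample."""
        return self.y1_all[: self.n1]

    @property
    def g1(self) -> np.ndarray:
        return self.g[: self.n1]

    @property
    def y2(self) -> np.ndarray:
        """Focal trait on its own (cohort 2) sample."""
        return self.y2_all[self._cohort2_idx]

    @property
    def g2(self) -> np.ndarray:
        return self.g[self._cohort2_idx]

    @property
    def y1_on_cohort2(self) -> np.ndarray:
        """Covariate values aligned with ``y2`` (regressor of the adjusted fit)."""
        return self.y1_all[self._cohort2_idx]

    @property
    def overlap(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(y1, y2, g) restricted to the overlap sample, for MANOVA."""
        s = slice(0, self.n_overlap)
        return self.y1_all[s], self.y2_all[s], self.g[s]


def simulate_genotypes(n: int, maf: float, rng: np.random.Generator) -> np.ndarray:
    """Draw n additive genotype scores Binomial(2, maf) under HWE."""
    if not 0 < maf <= 0.5:
        raise ValueError(f"maf must be in (0, 0.5], got {maf}")
    return rng.binomial(2, maf, size=n)


def effect_from_h2(h2: float, maf: float) -> float:
    """Per-allele effect size giving variance explained ``h2`` on a unit-variance trait.

    beta = sqrt(h2 / (2 maf (1-maf))), so beta^2 Var(G) = h2 exactly.
    """
    if not 0 <= h2 < 1:
        raise ValueError(f"h2 must be in [0, 1), got {h2}")
    if not 0 < maf <= 0.5:
        raise ValueError(f"maf must be in (0, 0.5], got {maf}")
    return float(np.sqrt(h2 / (2.0 * maf * (1.0 - maf))))


def simulate_replicate(config: ScenarioConfig, rng: np.random.Generator | None = None) -> StudyReplicate:
    """Generate one replicate of genotypes and bivariate traits."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_union = config.n_union
    g = simulate_genotypes(n_union, config.maf, rng)

    beta1 = effect_from_h2(config.h2_1, config.maf)
    beta2 = effect_from_h2(config.h2_2, config.maf)
    if config.direction == "opposite":
        beta2 = -beta2

    # residuals: unit total trait variance, residual correlation rho
    s1 = np.sqrt(1.0 - config.h2_1)
    s2 = np.sqrt(1.0 - config.h2_2)
    z = rng.standard_normal((n_union, 2))
    e1 = s1 * z[:, 0]
    e2 = s2 * (config.rho * z[:, 0] + np.sqrt(1.0 - config.rho**2) * z[:, 1])

    membership = np.empty(n_union, dtype="U7")
    membership[: config.n_overlap] = "overlap"
    membership[config.n_overlap : config.n1] = "only1"
    membership[config.n1 :] = "only2"

    return StudyReplicate(
        g=g,
        y1_all=beta1 * g + e1,
        y2_all=beta2 * g + e2,
        membership=membership,
        n1=config.n1,
        n2=config.n2,
        n_overlap=config.n_overlap,
    )


def scenario_grid(
    base: ScenarioConfig,
    axis: str,
    values: Iterable,
) -> list[ScenarioConfig]:
    """One config per value of ``axis`` (e.g. ``"h2_2"`` or ``"rho"``).

    All other fields are shared; seeds are offset deterministically so grid
    points use distinct streams. Illegal values raise, naming the entry.
    """
    if axis not in ScenarioConfig.__dataclass_fields__:
        raise ValueError(f"unknown scenario field {axis!r}")
    configs = []
    for i, v in enumerate(values):
        try:
            configs.append(replace(base, **{axis: v, "seed": (base.seed + 1 + i) % _SEED_MOD}))
        except ValueError as exc:
            raise ValueError(f"illegal {axis} value {v!r}: {exc}") from exc
    return configs


def export_replicate(rep: StudyReplicate, path) -> None:
    """Write one replicate as plain text (id, y1, y2, g, membership).

    y1/y2 are blank for individuals outside the respective cohort, so the
    table can be re-fit in external software for cross-checking.
    """
    in1 = np.zeros(len(rep.g), dtype=bool)
    in1[: rep.n1] = True
    in2 = np.zeros(len(rep.g), dtype=bool)
    in2[rep._cohort2_idx] = True
    with open(path, "w") as fh:
        fh.write("id\ty1\ty2\tg\tmembership\n")
        for i in range(len(rep.g)):
            y1 = f"{rep.y1_all[i]:.10g}" if in1[i] else "NA"
            y2 = f"{rep.y2_all[i]:.10g}" if in2[i] else "NA"
            fh.write(f"{i}\t{y1}\t{y2}\t{rep.g[i]}\t{rep.membership[i]}\n")
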