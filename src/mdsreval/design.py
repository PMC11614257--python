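"""Multi-stage survey-design arithmetic: design effect, finite-population
corrected stratum sample sizes, and probability-proportional-to-size
(PPS) allocation across regions.

The sampling frame is stratified by facility type (health centres vs
hospitals).  For each stratum the initial size is n0 = z^2 sigma^2 /
eps^2, corrected for the finite stratum population N via
n = n0 N / (n0 + N - 1), inflated by the design effect
deff = 1 + (m - 1) rho (mean cluster size m, intra-cluster correlation
rho), rounded up, and capped at N.  The stratum total is then allocated
to regions proportionally to their facility counts, integerized by the
largest-remainder rule so the total is conserved exactly.
"""

from __future__ import annotations

import math
from typing import Mapping

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ConfigError, MdsrEvalError

__all__ = [
    "DesignParams",
    "SamplingPlan",
    "design_effect",
    "stratum_sample_size",
    "pps_allocate",
    "build_sampling_plan",
]


class DesignParams(BaseModel):
    """Inputs to the sample-size computation.

    z is the normal critical value Z_{alpha/2}; sigma2 the pooled
    variance of the performance measure; epsilon the margin of error
    (same units as the measure); rho the intra-cluster correlation and
    m the mean cluster size feeding the design effect; N_strata maps
    each stratum (e.g. ``health_centre``, ``hospital``) to its
    population size.
    """

    model_config = ConfigDict(frozen=True)

    z: float = Field(gt=0)
    sigma2: float = Field(gt=0)
    epsilon: float = Field(gt=0)
    rho: float = Field(ge=0.0, le=1.0)
    m: float = Field(ge=1.0)
    N_strata: Mapping[str, int]

    @model_validator(mode="after")
    def _check(self) -> "DesignParams":
        if not self.N_strata:
            raise ConfigError("N_strata must not be empty")
        if any(n < 1 for n in self.N_strata.values()):
            raise ConfigError("every stratum population must be >= 1")
        return self

    @property
    def n0(self) -> float:
        """Initial (infinite-population) sample size z^2 sigma^2 / eps^2."""
        return (self.z**2) * self.sigma2 / (self.epsilon**2)

    @property
    def deff(self) -> float:
        return design_effect(self.m, self.rho)


class SamplingPlan(BaseModel):
    model_config = ConfigDict(frozen=True)

    deff: float
    n0: float
    n_strata: Mapping[str, int]
    n_total: int
    allocation: Mapping[str, int]


def design_effect(m: float, rho: float) -> float:
    """Variance inflation from clustering: deff = 1 + (m - 1) rho."""
    if m < 1:
        raise MdsrEvalError(f"mean cluster size m must be >= 1, got {m}")
    if not (0.0 <= rho <= 1.0):
        raise MdsrEvalError(f"intra-cluster correlation must be in [0, 1], got {rho}")
    return 1.0 + (m - 1.0) * rho


def stratum_sample_size(
    params: DesignParams, stratum: str, deff_before_fpc: bool = False
) -> int:
    """Final sample size for one stratum.

    Default order: finite-population correction first, then the design
    effect, then ceil, capped at the stratum population.  With
    ``deff_before_fpc`` the initial size is inflated before the FPC.
    """
    if stratum not in params.N_strata:
        raise MdsrEvalError(f"unknown stratum {stratum!r}")
    n_pop = params.N_strata[stratum]
    n0 = params.n0
    if deff_before_fpc:
        n0 *= params.deff
        n = n0 * n_pop / (n0 + n_pop - 1)
    else:
        n = params.deff * (n0 * n_pop / (n0 + n_pop - 1))
    return min(math.ceil(n), n_pop)


def pps_allocate(n: int, region_sizes: Mapping[str, float]) -> dict[str, int]:
    """Allocate n sampling units across regions proportionally to size.

    Ideal shares n * N_r / N are integerized by the largest-remainder
    rule, so the allocation sums to n exactly and every region is within
    one unit of its ideal share.  Ties in the remainder break by region
    name for determinism.
    """
    if n < 0:
        raise MdsrEvalError("total sample size must be >= 0")
    if not region_sizes:
        raise MdsrEvalError("region_sizes must not be empty")
    total = float(sum(region_sizes.values()))
    if total <= 0:
        raise MdsrEvalError("region sizes must sum to a positive total")
    ideal = {r: n * s / total for r, s in region_sizes.items()}
    alloc = {r: math.floor(v) for r, v in ideal.items()}
    remainder = n - sum(alloc.values())
    order = sorted(region_sizes, key=lambda r: (-(ideal[r] - alloc[r]), r))
    for r in order[:remainder]:
        alloc[r] += 1
    return alloc


def build_sampling_plan(
    params: DesignParams,
    region_sizes: Mapping[str, Mapping[str, float]] | Mapping[str, float] | None = None,
    deff_before_fpc: bool = False,
) -> SamplingPlan:
    """Full plan: per-stratum sizes plus (optionally) a PPS allocation.

    ``region_sizes`` may map region -> size (the combined total is
    allocated) or stratum -> region -> size (allocated per stratum and
    summed per region).
    """
    n_strata = {
        s: stratum_sample_size(params, s, deff_before_fpc) for s in params.N_strata
    }
    n_total = sum(n_strata.values())
    allocation: dict[str, int] = {}
    if region_sizes:
        first = next(iter(region_sizes.values()))
        if isinstance(first, Mapping):  # per-stratum region sizes
            for stratum, sizes in region_sizes.items():
                if stratum not in n_strata:
                    raise MdsrEvalError(f"unknown stratum {stratum!r} in region_sizes")
                for r, k in pps_allocate(n_strata[stratum], sizes).items():
                    allocation[r] = allocation.get(r, 0) + k
        else:
            allocation = pps_allocate(n_total, region_sizes)  # type: ignore[arg-type]
    return SamplingPlan(
        deff=params.deff,
        n0=params.n0,
        n_strata=n_strata,
        n_total=n_total,
        allocation=allocation,
    )
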