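"""Synthetic data generators emulating the study's statistical structure.

Prey species are independent bivariate-normal clouds with specified moments;
consumers are draws from the mixing-model forward process (a known diet
vector over TEF-adjusted sources); and any sample can be affinely
moment-matched so that its sample mean and SD (n−1) reproduce published
summary statistics exactly.  Everything is seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import tables
from .grouping import SourceGroup
from .isotopes import IsotopeRecord, TEFSpec
from .simm import mixture_moments


@dataclass(frozen=True)
class SpeciesSpec:
    """Generator spec for one prey species (independent isotopes)."""

    label: str
    n: int
    d13C_mean: float
    d13C_sd: float
    d15N_mean: float
    d15N_sd: float
    c_to_n: float = 3.1

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.d13C_sd < 0 or self.d15N_sd < 0:
            raise ValueError("SDs must be >= 0")


def moment_match(
    values: Sequence[float], target_mean: float, target_sd: float
) -> np.ndarray:
    """Affine transform so the sample mean and SD (n−1) equal the targets exactly.

    Requires ≥ 2 values, with nonzero spread unless ``target_sd`` is 0.
    Idempotent on already-matched data.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if target_sd < 0:
        raise ValueError("target_sd must be >= 0")
    s = x.std(ddof=1)
    if s == 0:
        if target_sd > 0:
            raise ValueError("zero input spread cannot be scaled to a positive SD")
        return np.full_like(x, target_mean)
    return (x - x.mean()) / s * target_sd + target_mean


def gen_prey(
    specs: Sequence[SpeciesSpec],
    seed: int | np.random.SeedSequence | None = None,
    exact: bool = False,
) -> list[IsotopeRecord]:
    """Per species, n independent normal draws per isotope.

    With ``exact=True`` each species sample is moment-matched so its summary
    reproduces the spec moments exactly (requires n ≥ 2 per species).
    """
    rng = np.random.default_rng(seed)
    out = []
    for sp in specs:
        c = rng.normal(sp.d13C_mean, sp.d13C_sd, sp.n)
        nvals = rng.normal(sp.d15N_mean, sp.d15N_sd, sp.n)
        if exact:
            c = moment_match(c, sp.d13C_mean, sp.d13C_sd)
            nvals = moment_match(nvals, sp.d15N_mean, sp.d15N_sd)
        for i in range(sp.n):
            out.append(
                IsotopeRecord(
                    record_id=f"{sp.label}_{i + 1}",
                    category="prey",
                    label=sp.label,
                    tissue="muscle",
                    sex="unknown",
                    d13C=float(c[i]),
                    d15N=float(nvals[i]),
                    c_to_n=sp.c_to_n,
                )
            )
    return out


def reference_prey_specs() -> list[SpeciesSpec]:
    """Species specs carrying the published Northwest Atlantic prey moments."""
    return [
        SpeciesSpec(label=lab, n=v[0], d13C_mean=v[1], d13C_sd=v[2],
                    d15N_mean=v[3], d15N_sd=v[4], c_to_n=v[5])
        for lab, v in tables.PREY_SPECIES.items()
    ]


def reference_prey(seed: int | None = 0, exact: bool = True) -> list[IsotopeRecord]:
    """Synthetic prey records whose per-species summaries match the published
    moments (exactly, by default)."""
    return gen_prey(reference_prey_specs(), seed=seed, exact=exact)


def gen_consumers(
    p_true: Sequence[float],
    groups: Sequence[SourceGroup],
    tef: TEFSpec,
    n: int,
    residual_sd: Sequence[float] = (0.0, 0.0),
    seed: int | np.random.SeedSequence | None = None,
    tissue: str = "vibrissae",
    id_prefix: str = "SIM",
) -> list[IsotopeRecord]:
    """Forward-model consumers: Normal(mixture mean, mixture var + residual²).

    Ground truth for parameter-recovery checks; isotopes are independent.
    """
    mean, var = mixture_moments(np.asarray(p_true, dtype=float), groups, tef)
    total_sd = np.sqrt(var + np.asarray(residual_sd, dtype=float) ** 2)
    rng = np.random.default_rng(seed)
    draws = rng.normal(mean, total_sd, size=(n, 2))
    return [
        IsotopeRecord(
            record_id=f"{id_prefix}{i + 1:03d}",
            category="consumer",
            label=f"{id_prefix}{i + 1:03d}",
            tissue=tissue,
            sex="unknown",
            d13C=float(draws[i, 0]),
            d15N=float(draws[i, 1]),
            c_to_n=3.0,
        )
    for i in range(n)
    ]


def matched_consumers(
    tissue: str, seed: int | np.random.SeedSequence | None = None
) -> list[IsotopeRecord]:
    """Synthetic pups whose tissue summary reproduces the published moments.

    Draws n standard-normal values per isotope and moment-matches them to the
    published all-pup mean ± SD for the tissue (25 vibrissae / 19 lanugo
    individuals).  Sexes follow the published counts; shared ids ("P01", …)
    let the vibrissae and lanugo sets pair by individual.
    """
    n, c_mean, c_sd, n_mean, n_sd = tables.consumer_moments(tissue)
    rng = np.random.default_rng(seed)
    c = moment_match(rng.normal(size=n), c_mean, c_sd)
    nv = moment_match(rng.normal(size=n), n_mean, n_sd)
    n_m = tables.CONSUMER_MOMENTS[tissue]["M"][0]
    n_f = tables.CONSUMER_MOMENTS[tissue]["F"][0]
    sexes = ["M"] * n_m + ["F"] * n_f + ["unknown"] * (n - n_m - n_f)
    return [
        IsotopeRecord(
            record_id=f"P{i + 1:02d}",
            category="consumer",
            label=f"P{i + 1:02d}",
            tissue=tissue,
            sex=sexes[i],
            d13C=float(c[i]),
            d15N=float(nv[i]),
            c_to_n=3.0,
        )
        for i in range(n)
    ]
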