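"""Prey source aggregation: Ward clustering of species and pooled group moments.

Mixing models lose discriminatory power as the number of sources grows, so
isotopically similar prey species are combined before modelling: a Ward
hierarchical clustering of the species mean vectors cut at six groups, and a
coarser three-group partition (squids / sand lance / demersal fishes) drawn
on ecological rather than statistical grounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import yaml
from scipy.cluster.hierarchy import fcluster, linkage

from .isotopes import IsotopeRecord, SpeciesSummary, summarize_species


@dataclass(frozen=True)
class GroupingScheme:
    """A partition of species labels into named source groups."""

    name: str
    assignment: Mapping[str, str]  # species label -> group name
    origin: str  # "ward" | "manual"

    def __post_init__(self) -> None:
        if self.origin not in ("ward", "manual"):
            raise ValueError(f"unknown origin {self.origin!r}")
        if not self.assignment:
            raise ValueError("empty assignment")

    @property
    def groups(self) -> list[str]:
        """Group names, in first-appearance order of the assignment."""
        seen: list[str] = []
        for g in self.assignment.values():
            if g not in seen:
                seen.append(g)
        return seen

    def members(self, group: str) -> list[str]:
        return [s for s, g in self.assignment.items() if g == group]


@dataclass(frozen=True)
class SourceGroup:
    """An aggregated prey source with pooled per-isotope moments."""

    name: str
    members: tuple[str, ...]
    n: int
    d13C_mean: float
    d13C_sd: float
    d15N_mean: float
    d15N_sd: float

    def __post_init__(self) -> None:
        for sd in (self.d13C_sd, self.d15N_sd):
            if not math.isnan(sd) and sd < 0:
                raise ValueError("SD must be >= 0")

    @property
    def sd_defined(self) -> bool:
        return not (math.isnan(self.d13C_sd) or math.isnan(self.d15N_sd))


def _pooled_axis_scale(summaries: Sequence[SpeciesSummary]) -> np.ndarray:
    """Pooled within-species SD per isotope, used to standardize the axes."""
    n = np.array([s.n for s in summaries], dtype=float)
    dof = n - 1.0
    if dof.sum() <= 0:
        return np.ones(2)
    sds = np.array(
        [[0.0 if s.n == 1 else s.d13C_sd, 0.0 if s.n == 1 else s.d15N_sd] for s in summaries]
    )
    return np.sqrt((dof[:, None] * sds**2).sum(axis=0) / dof.sum())


def ward_cluster(summaries: Sequence[SpeciesSummary], k: int) -> GroupingScheme:
    """Agglomerative Ward clustering of species mean vectors, cut at ``k``.

    Species are points (δ13C mean, δ15N mean); each axis is standardized by
    the pooled within-species SD so that both isotopes' observed variability
    weighs in (clustering raw ‰ coordinates over-weights the isotope with the
    larger numeric spread).  Group names concatenate sorted member labels.
    """
    summaries = list(summaries)
    if not 1 <= k <= len(summaries):
        raise ValueError(f"k={k} out of range [1, {len(summaries)}]")
    X = np.array([[s.d13C_mean, s.d15N_mean] for s in summaries])
    scale = _pooled_axis_scale(summaries)
    scale = np.where(scale > 0, scale, 1.0)
    Z = linkage(X / scale, method="ward")
    flat = fcluster(Z, t=k, criterion="maxclust")
    members: dict[int, list[str]] = {}
    for s, c in zip(summaries, flat):
        members.setdefault(int(c), []).append(s.label)
    assignment = {}
    for labs in members.values():
        gname = " + ".join(sorted(labs))
        for lab in labs:
            assignment[lab] = gname
    # preserve input species order in the mapping
    assignment = {s.label: assignment[s.label] for s in summaries}
    return GroupingScheme(name=f"ward_k{k}", assignment=assignment, origin="ward")


def manual_grouping(
    assignment: Mapping[str, str],
    species: Iterable[str] | None = None,
    name: str = "manual",
) -> GroupingScheme:
    """Validate a hand-specified species -> group map.

    If ``species`` is given, the map must cover exactly that set (an omitted
    or extra species is an error).
    """
    if species is not None:
        want = set(species)
        have = set(assignment)
        missing = want - have
        extra = have - want
        if missing:
            raise ValueError(f"species not assigned to any group: {sorted(missing)}")
        if extra:
            raise ValueError(f"assignment covers unknown species: {sorted(extra)}")
    return GroupingScheme(name=name, assignment=dict(assignment), origin="manual")


def pool_group_stats(
    data: Sequence[Union[SpeciesSummary, IsotopeRecord]],
    scheme: GroupingScheme,
) -> list[SourceGroup]:
    """Pooled per-group moments, identical for raw records and summaries.

    Group mean is the n-weighted mean of member means; group variance is the
    exact variance of the concatenated sample,
    ``[Σ(nᵢ−1)sᵢ² + Σnᵢ(mᵢ−m̄)²] / (N−1)``.  A group with total n < 2 gets
    NaN SDs (undefined, never zero).
    """
    data = list(data)
    if data and isinstance(data[0], IsotopeRecord):
        summaries: list[SpeciesSummary] = summarize_species(data)  # type: ignore[arg-type]
    else:
        summaries = list(data)  # type: ignore[assignment]
    present = {s.label for s in summaries}
    uncovered = present - set(scheme.assignment)
    if uncovered:
        raise ValueError(f"grouping scheme does not cover species: {sorted(uncovered)}")
    out = []
    for gname in scheme.groups:
        membs = [s for s in summaries if scheme.assignment[s.label] == gname]
        if not membs:
            continue
        n = np.array([s.n for s in membs], dtype=float)
        N = n.sum()
        stats = {}
        for iso in ("d13C", "d15N"):
            m = np.array([getattr(s, f"{iso}_mean") for s in membs])
            sd = np.array(
                [0.0 if s.n == 1 else getattr(s, f"{iso}_sd") for s in membs]
            )
            wm = float((n * m).sum() / N)
            if N < 2:
                stats[iso] = (wm, float("nan"))
            else:
                var = (((n - 1.0) * sd**2).sum() + (n * (m - wm) ** 2).sum()) / (N - 1.0)
                stats[iso] = (wm, float(np.sqrt(var)))
        out.append(
            SourceGroup(
                name=gname,
                members=tuple(s.label for s in membs),
                n=int(N),
                d13C_mean=stats["d13C"][0],
                d13C_sd=stats["d13C"][1],
                d15N_mean=stats["d15N"][0],
                d15N_sd=stats["d15N"][1],
            )
        )
    return out


def load_groupings(path=None) -> dict[str, GroupingScheme]:
    """Load named manual grouping schemes from YAML.

    Default: the packaged ``groupings.yaml`` shipping the ecological
    three-source partition.
    """
    if path is None:
        from importlib.resources import files

        text = (files("sealsimm") / "data" / "groupings.yaml").read_text()
    else:
        text = open(path).read()
    raw = yaml.safe_load(text)
    return {
        name: GroupingScheme(name=name, assignment=dict(mapping), origin="manual")
        for name, mapping in raw.items()
    }
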