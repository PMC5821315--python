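"""Core isotope data model: records, δ-notation math, summaries, TEF averaging, CSV I/O.

Stable carbon and nitrogen isotope compositions are expressed in δ notation
(per mil, ‰) relative to international standards (VPDB for carbon,
atmospheric N2 for nitrogen).  A trophic enrichment factor (TEF) is the
per-isotope offset (mean ± SD) between a consumer tissue and its diet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CONSUMER_TISSUES = ("vibrissae", "lanugo")
PREY_TISSUE = "muscle"
TEF_TISSUES = ("vibrissae", "hair")
SEXES = ("M", "F", "unknown")

#: CSV column schemas (External interface).
CONSUMER_COLUMNS = ("id", "tissue", "sex", "d13C", "d15N", "c_to_n")
PREY_COLUMNS = ("species", "d13C", "d15N", "c_to_n")
TEF_COLUMNS = ("provenance", "tissue", "d13C_mean", "d13C_sd", "d15N_mean", "d15N_sd", "n")


class CsvFormatError(ValueError):
    """A CSV input is malformed (missing column, unparseable cell)."""


@dataclass(frozen=True)
class IsotopeRecord:
    """One tissue (consumer) or muscle (prey) measurement in (δ13C, δ15N) space.

    ``label`` is the species name for prey and the individual id for consumers.
    ``c_to_n`` is the elemental C/N mass ratio (quality-control covariate),
    optional.
    """

    record_id: str
    category: str  # "consumer" | "prey"
    label: str
    tissue: str  # vibrissae | lanugo | muscle
    sex: str  # M | F | unknown
    d13C: float
    d15N: float
    c_to_n: float | None = None

    def __post_init__(self) -> None:
        if self.category not in ("consumer", "prey"):
            raise ValueError(f"unknown category {self.category!r}")
        if not (math.isfinite(self.d13C) and math.isfinite(self.d15N)):
            raise ValueError(f"record {self.record_id!r}: non-finite isotope value")
        if self.c_to_n is not None and not (self.c_to_n > 0):
            raise ValueError(f"record {self.record_id!r}: C/N must be positive")
        if self.sex not in SEXES:
            raise ValueError(f"record {self.record_id!r}: unknown sex {self.sex!r}")
        if (self.tissue == PREY_TISSUE) != (self.category == "prey"):
            raise ValueError(
                f"record {self.record_id!r}: tissue {self.tissue!r} inconsistent "
                f"with category {self.category!r} (muscle iff prey)"
            )
        if self.category == "consumer" and self.tissue not in CONSUMER_TISSUES:
            raise ValueError(f"record {self.record_id!r}: unknown consumer tissue {self.tissue!r}")

    @property
    def xy(self) -> tuple[float, float]:
        """(δ13C, δ15N) coordinate pair."""
        return (self.d13C, self.d15N)


@dataclass(frozen=True)
class SpeciesSummary:
    """Per-label mean ± SD of δ13C and δ15N (SD with n−1 denominator).

    When n = 1 the SDs are NaN and :attr:`sd_defined` is False; an undefined
    SD is never silently collapsed to zero.
    """

    label: str
    n: int
    d13C_mean: float
    d13C_sd: float
    d15N_mean: float
    d15N_sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for sd in (self.d13C_sd, self.d15N_sd):
            if not math.isnan(sd) and sd < 0:
                raise ValueError("SD must be >= 0")

    @property
    def sd_defined(self) -> bool:
        return self.n > 1 and not math.isnan(self.d13C_sd)


@dataclass(frozen=True)
class TEFSpec:
    """Trophic enrichment factor for one tissue: per-isotope mean ± SD.

    ``n`` is the sample size behind an experimentally determined value and
    may be absent for meta-analytic or ecosystem-average values.
    """

    provenance: str
    tissue: str  # vibrissae | hair
    d13C_mean: float
    d13C_sd: float
    d15N_mean: float
    d15N_sd: float
    n: int | None = None

    def __post_init__(self) -> None:
        if self.tissue not in TEF_TISSUES:
            raise ValueError(f"unknown TEF tissue {self.tissue!r}")
        if self.d13C_sd < 0 or self.d15N_sd < 0:
            raise ValueError("TEF SDs must be >= 0")
        if self.n is not None and self.n < 1:
            raise ValueError("TEF n must be >= 1 when present")


def tef_tissue_for(consumer_tissue: str) -> str:
    """Map a consumer tissue to the TEF table tissue (lanugo is hair)."""
    if consumer_tissue == "vibrissae":
        return "vibrissae"
    if consumer_tissue == "lanugo":
        return "hair"
    raise ValueError(f"no TEF tissue for {consumer_tissue!r}")


def delta_from_ratio(r_sample: float, r_standard: float) -> float:
    """δ value (‰) from a sample and standard isotope ratio.

    δX = (R_sample / R_standard − 1) × 1000, where R is 13C/12C or 15N/14N.
    """
    if not (r_sample > 0 and r_standard > 0):
        raise ValueError("isotope ratios must be positive")
    return (r_sample / r_standard - 1.0) * 1000.0


def summarize_species(records: Iterable[IsotopeRecord]) -> list[SpeciesSummary]:
    """One mean ± SD summary per label, in first-appearance order.

    All records must share a category.  SDs use the n−1 denominator; a
    single-record label gets NaN SDs (flagged undefined).
    """
    records = list(records)
    if not records:
        return []
    cats = {r.category for r in records}
    if len(cats) > 1:
        raise ValueError(f"records mix categories: {sorted(cats)}")
    by_label: dict[str, list[IsotopeRecord]] = {}
    for r in records:
        by_label.setdefault(r.label, []).append(r)
    out = []
    for label, rs in by_label.items():
        c = np.array([r.d13C for r in rs])
        n_vals = np.array([r.d15N for r in rs])
        n = len(rs)
        out.append(
            SpeciesSummary(
                label=label,
                n=n,
                d13C_mean=float(c.mean()),
                d13C_sd=float(c.std(ddof=1)) if n > 1 else float("nan"),
                d15N_mean=float(n_vals.mean()),
                d15N_sd=float(n_vals.std(ddof=1)) if n > 1 else float("nan"),
            )
        )
    return out


def average_tefs(entries: Sequence[TEFSpec]) -> TEFSpec:
    """Combine experimentally determined TEFs into a single mean ± SD.

    The mean is the sample-size-weighted mean of the entry means and the SD
    is the pooled within-study SD, sqrt(Σ(nᵢ−1)sᵢ² / Σ(nᵢ−1)).  All entries
    must carry a sample size and share a tissue.  A single entry is returned
    unchanged.
    """
    if not entries:
        raise ValueError("need at least one TEF entry")
    tissues = {e.tissue for e in entries}
    if len(tissues) > 1:
        raise ValueError(f"cannot average TEFs across tissues: {sorted(tissues)}")
    if any(e.n is None for e in entries):
        missing = [e.provenance for e in entries if e.n is None]
        raise ValueError(f"TEF entries without sample size: {missing}")
    if len(entries) == 1:
        return entries[0]
    n = np.array([e.n for e in entries], dtype=float)
    dof = (n - 1.0).sum()
    if dof <= 0:
        raise ValueError("pooled SD needs at least one entry with n > 1")

    def _pool(means: np.ndarray, sds: np.ndarray) -> tuple[float, float]:
        wm = float((n * means).sum() / n.sum())
        ps = float(np.sqrt(((n - 1.0) * sds**2).sum() / dof))
        return wm, ps

    c_mean, c_sd = _pool(
        np.array([e.d13C_mean for e in entries]), np.array([e.d13C_sd for e in entries])
    )
    n_mean, n_sd = _pool(
        np.array([e.d15N_mean for e in entries]), np.array([e.d15N_sd for e in entries])
    )
    return TEFSpec(
        provenance="mean of: " + "; ".join(e.provenance for e in entries),
        tissue=entries[0].tissue,
        d13C_mean=c_mean,
        d13C_sd=c_sd,
        d15N_mean=n_mean,
        d15N_sd=n_sd,
        n=int(n.sum()),
    )


def round_half_up(x: float, decimals: int = 1) -> float:
    """Display rounding: half-up to the given number of decimals."""
    q = 10.0**decimals
    return math.floor(abs(x) * q + 0.5) / q * (1 if x >= 0 else -1)


# ---------------------------------------------------------------------------
# CSV I/O


def _parse_float(value, column: str, row: int, path, required: bool = True) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        if required:
            raise CsvFormatError(f"{path}: row {row}: missing value in column {column!r}")
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise CsvFormatError(
            f"{path}: row {row}: cannot parse {value!r} in column {column!r}"
        ) from None


def read_records(path, category: str) -> list[IsotopeRecord]:
    """Read consumer or prey records from CSV.

    Consumer files have columns ``id,tissue,sex,d13C,d15N,c_to_n``; prey
    files ``species,d13C,d15N,c_to_n``.  Errors name the offending row
    (1-based, excluding the header).
    """
    if category not in ("consumer", "prey"):
        raise ValueError(f"unknown category {category!r}")
    df = pd.read_csv(path, dtype=str)
    required = set(CONSUMER_COLUMNS[:5]) if category == "consumer" else set(PREY_COLUMNS[:3])
    missing = required - set(df.columns)
    if missing:
        raise CsvFormatError(f"{path}: missing required column(s) {sorted(missing)}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        c_to_n = _parse_float(row.get("c_to_n"), "c_to_n", i, path, required=False)
        if category == "consumer":
            rec = IsotopeRecord(
                record_id=str(row["id"]),
                category="consumer",
                label=str(row["id"]),
                tissue=str(row["tissue"]),
                sex=str(row["sex"]),
                d13C=_parse_float(row["d13C"], "d13C", i, path),
                d15N=_parse_float(row["d15N"], "d15N", i, path),
                c_to_n=c_to_n,
            )
        else:
            rec = IsotopeRecord(
                record_id=f"{row['species']}_{i}",
                category="prey",
                label=str(row["species"]),
                tissue=PREY_TISSUE,
                sex="unknown",
                d13C=_parse_float(row["d13C"], "d13C", i, path),
                d15N=_parse_float(row["d15N"], "d15N", i, path),
                c_to_n=c_to_n,
            )
        out.append(rec)
    return out


def write_records(records: Sequence[IsotopeRecord], path) -> None:
    """Write records to CSV using the schema matching their category."""
    records = list(records)
    if not records:
        raise ValueError("no records to write")
    cats = {r.category for r in records}
    if len(cats) > 1:
        raise ValueError("cannot mix consumer and prey records in one file")
    path = Path(path)
    if records[0].category == "consumer":
        df = pd.DataFrame(
            {
                "id": [r.record_id for r in records],
                "tissue": [r.tissue for r in records],
                "sex": [r.sex for r in records],
                "d13C": [repr(r.d13C) for r in records],
                "d15N": [repr(r.d15N) for r in records],
                "c_to_n": ["" if r.c_to_n is None else repr(r.c_to_n) for r in records],
            }
        )
    else:
        df = pd.DataFrame(
            {
                "species": [r.label for r in records],
                "d13C": [repr(r.d13C) for r in records],
                "d15N": [repr(r.d15N) for r in records],
                "c_to_n": ["" if r.c_to_n is None else repr(r.c_to_n) for r in records],
            }
        )
    df.to_csv(path, index=False)


def read_tefs(path) -> list[TEFSpec]:
    """Read TEF candidates from CSV (``provenance,tissue,d13C_mean,...,n``)."""
    df = pd.read_csv(path, dtype=str)
    missing = set(TEF_COLUMNS[:6]) - set(df.columns)
    if missing:
        raise CsvFormatError(f"{path}: missing required column(s) {sorted(missing)}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        n_raw = row.get("n")
        n = None
        if n_raw not in (None, "") and not (isinstance(n_raw, float) and math.isnan(n_raw)):
            n = int(float(n_raw))
        out.append(
            TEFSpec(
                provenance=str(row["provenance"]),
                tissue=str(row["tissue"]),
                d13C_mean=_parse_float(row["d13C_mean"], "d13C_mean", i, path),
                d13C_sd=_parse_float(row["d13C_sd"], "d13C_sd", i, path),
                d15N_mean=_parse_float(row["d15N_mean"], "d15N_mean", i, path),
                d15N_sd=_parse_float(row["d15N_sd"], "d15N_sd", i, path),
                n=n,
            )
        )
    return out


def write_tefs(tefs: Sequence[TEFSpec], path) -> None:
    df = pd.DataFrame(
        {
            "provenance": [t.provenance for t in tefs],
            "tissue": [t.tissue for t in tefs],
            "d13C_mean": [repr(t.d13C_mean) for t in tefs],
            "d13C_sd": [repr(t.d13C_sd) for t in tefs],
            "d15N_mean": [repr(t.d15N_mean) for t in tefs],
            "d15N_sd": [repr(t.d15N_sd) for t in tefs],
            "n": ["" if t.n is None else str(t.n) for t in tefs],
        }
    )
    df.to_csv(path, index=False)
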