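"""Classical comparisons: tissue correlations, t-tests, one-way ANOVA with
Tukey HSD and a compact-letter display for prey species.

These are the frequentist checks run before diet modelling: whether the two
in-utero pup tissues (vibrissae, lanugo) agree, whether isotope values differ
by pup sex, and which prey species are isotopically distinguishable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .isotopes import IsotopeRecord, summarize_species


@dataclass(frozen=True)
class PairedTissueSet:
    """Vibrissae and lanugo (δ13C, δ15N) pairs for one individual."""

    individual: str
    vibrissae: tuple[float, float]
    lanugo: tuple[float, float]


@dataclass(frozen=True)
class AnovaLetters:
    """One-way ANOVA with all-pairs Tukey HSD and a compact-letter display.

    ``letters`` maps label -> letter string; two labels share a letter iff
    their Tukey-adjusted pairwise comparison is non-significant at ``alpha``.
    """

    isotope: str
    f_stat: float
    p_value: float
    alpha: float
    pairwise_p: pd.DataFrame
    letters: dict[str, str]


def paired_tissue_sets(records: Iterable[IsotopeRecord]) -> list[PairedTissueSet]:
    """Pair vibrissae and lanugo records by individual id.

    Individuals with only one tissue are dropped; an individual with
    duplicate records for a tissue is an error.
    """
    by_ind: dict[str, dict[str, IsotopeRecord]] = {}
    for r in records:
        if r.category != "consumer":
            continue
        slot = by_ind.setdefault(r.label, {})
        if r.tissue in slot:
            raise ValueError(f"individual {r.label!r} has duplicate {r.tissue} records")
        slot[r.tissue] = r
    out = []
    for ind in sorted(by_ind):
        slot = by_ind[ind]
        if "vibrissae" in slot and "lanugo" in slot:
            out.append(
                PairedTissueSet(ind, slot["vibrissae"].xy, slot["lanugo"].xy)
            )
    return out


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation and two-sided p (t-distribution transform)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def t_test(x: Sequence[float], y: Sequence[float], paired: bool = False) -> tuple[float, float]:
    """Two-sided t-test: paired on differences, unpaired in the Welch form."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if x.shape != y.shape:
            raise ValueError("paired test needs equal lengths")
        if len(x) < 2:
            raise ValueError("need at least 2 pairs")
        d = x - y
        if np.allclose(d.std(ddof=1), 0):
            # all differences equal: t is 0 (no shift) or infinite (constant shift)
            if np.allclose(d.mean(), 0):
                return 0.0, 1.0
            return float(np.inf) * np.sign(d.mean()), 0.0
        res = stats.ttest_rel(x, y)
    else:
        if len(x) < 2 or len(y) < 2:
            raise ValueError("need at least 2 observations per arm")
        res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def compact_letter_display(
    labels: Sequence[str], significant_pairs: Iterable[tuple[str, str]]
) -> dict[str, str]:
    """Assign letters so labels share a letter iff not in ``significant_pairs``.

    Insert-and-absorb: start from one set holding all labels; for every
    significantly different pair split each set containing both, then drop
    sets that became subsets of another.  Letters are assigned to the final
    sets ordered by their earliest label in ``labels``.
    """
    labels = list(labels)
    order = {lab: i for i, lab in enumerate(labels)}
    sets: list[set[str]] = [set(labels)]
    for a, b in significant_pairs:
        new_sets: list[set[str]] = []
        for s in sets:
            if a in s and b in s:
                new_sets.append(s - {a})
                new_sets.append(s - {b})
            else:
                new_sets.append(s)
        # absorb: drop empty sets, strict subsets of another set, and duplicates
        new_sets = [s for s in new_sets if s]
        kept: list[set[str]] = []
        for s in new_sets:
            if any(s < t for t in new_sets) or s in kept:
                continue
            kept.append(s)
        sets = kept
    sets.sort(key=lambda s: min(order[lab] for lab in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lab: "" for lab in labels}
    for i, s in enumerate(sets):
        for lab in s:
            out[lab] += alphabet[i % len(alphabet)]
    return out


def anova_tukey_letters(
    values_by_label: Mapping[str, Sequence[float]],
    isotope: str = "",
    alpha: float = 0.05,
) -> AnovaLetters:
    """One-way ANOVA with Tukey HSD post-hoc comparisons and letter codes.

    ``values_by_label`` maps group label to raw values (each group n ≥ 2).
    Tukey HSD uses the studentized range on the pooled ANOVA residual mean
    square (Tukey–Kramer at unequal n).
    """
    labels = list(values_by_label)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    groups = [np.asarray(values_by_label[lab], dtype=float) for lab in labels]
    for lab, g in zip(labels, groups):
        if len(g) < 2:
            raise ValueError(f"group {lab!r} has n < 2")
    f_stat, p_value = stats.f_oneway(*groups)
    tukey = stats.tukey_hsd(*groups)
    pmat = pd.DataFrame(tukey.pvalue, index=labels, columns=labels)
    sig = [
        (labels[i], labels[j])
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
        if tukey.pvalue[i, j] < alpha
    ]
    letters = compact_letter_display(labels, sig)
    return AnovaLetters(
        isotope=isotope,
        f_stat=float(f_stat),
        p_value=float(p_value),
        alpha=alpha,
        pairwise_p=pmat,
        letters=letters,
    )


def species_report(
    records: Iterable[IsotopeRecord], alpha: float = 0.05
) -> pd.DataFrame:
    """Species summary table: n, mean ± SD and Tukey letters per isotope."""
    records = list(records)
    summaries = summarize_species(records)
    by_label: dict[str, list[IsotopeRecord]] = {}
    for r in records:
        by_label.setdefault(r.label, []).append(r)
    letters = {}
    for iso, attr in (("d13C", "d13C"), ("d15N", "d15N")):
        vals = {lab: [getattr(r, attr) for r in rs] for lab, rs in by_label.items()}
        letters[iso] = anova_tukey_letters(vals, isotope=iso, alpha=alpha).letters
    rows = []
    for s in summaries:
        rows.append(
            {
                "species": s.label,
                "n": s.n,
                "d13C_mean": s.d13C_mean,
                "d13C_sd": s.d13C_sd,
                "d13C_letters": letters["d13C"][s.label],
                "d15N_mean": s.d15N_mean,
                "d15N_sd": s.d15N_sd,
                "d15N_letters": letters["d15N"][s.label],
            }
        )
    return pd.DataFrame(rows)
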