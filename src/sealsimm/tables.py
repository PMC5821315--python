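"""Published reference inputs for the gray seal maternal-diet analysis.

The analysis operates on summary statistics published for the Northwest
Atlantic system: prey species isotope moments, candidate trophic enrichment
factors (TEFs), gray seal pup tissue moments, and scat-derived diet
proportions used as an informative prior.  These values are inputs to the
pipeline, bundled so every stage runs without external data.
"""

from __future__ import annotations

from .isotopes import SpeciesSummary, TEFSpec, average_tefs, tef_tissue_for

#: Prey species summary statistics: label -> (n, δ13C mean, δ13C SD, δ15N mean,
#: δ15N SD, C/N mean, C/N SD).  Muscle tissue, Northwest Atlantic, 2016.
PREY_SPECIES: dict[str, tuple[int, float, float, float, float, float, float]] = {
    "longfin squid": (5, -17.2, 0.3, 10.1, 1.2, 3.1, 0.0),
    "shortfin squid": (5, -17.1, 0.4, 8.0, 0.5, 3.1, 0.0),
    "sand lance": (7, -19.9, 0.5, 9.5, 1.7, 3.1, 0.0),
    "Atlantic cod": (5, -17.6, 0.7, 12.8, 0.4, 3.1, 0.0),
    "red hake": (5, -15.5, 0.4, 15.4, 0.4, 3.1, 0.0),
    "silver hake": (5, -15.8, 0.5, 16.0, 0.3, 3.0, 0.0),
    "thorny skate": (2, -15.8, 0.7, 12.0, 0.8, 3.2, 0.1),
    "white hake": (5, -17.0, 1.2, 12.9, 0.3, 3.1, 0.0),
    "winter flounder": (5, -16.5, 0.6, 14.9, 0.6, 3.1, 0.0),
    "winter skate": (5, -16.9, 0.4, 13.9, 0.2, 3.0, 0.0),
}

#: Ecological three-source partition (not a dendrogram cut): squids,
#: sand lance, and a pooled demersal-fishes group.
THREE_SOURCE_ASSIGNMENT: dict[str, str] = {
    "longfin squid": "squid",
    "shortfin squid": "squid",
    "sand lance": "sand lance",
    "Atlantic cod": "demersal fishes",
    "red hake": "demersal fishes",
    "silver hake": "demersal fishes",
    "thorny skate": "demersal fishes",
    "white hake": "demersal fishes",
    "winter flounder": "demersal fishes",
    "winter skate": "demersal fishes",
}

#: Experimentally determined phocid TEFs (captive feeding studies):
#: per tissue, δ15N and δ13C mean ± SD with study sample size.
EXPERIMENTAL_TEF_ENTRIES: tuple[TEFSpec, ...] = (
    TEFSpec("Hobson 1996 (phocids)", "vibrissae", d13C_mean=3.2, d13C_sd=0.2,
            d15N_mean=2.8, d15N_sd=0.1, n=7),
    TEFSpec("Beltran 2016 (phocids)", "vibrissae", d13C_mean=3.4, d13C_sd=0.5,
            d15N_mean=3.2, d15N_sd=0.5, n=8),
    TEFSpec("Hobson 1996 (phocids)", "hair", d13C_mean=2.8, d13C_sd=0.5,
            d15N_mean=3.0, d15N_sd=0.4, n=10),
    TEFSpec("Lesage 2001 (gray seal)", "hair", d13C_mean=2.3, d13C_sd=0.1,
            d15N_mean=2.3, d15N_sd=0.8, n=2),
)


def post_tef(tissue: str) -> TEFSpec:
    """Ecosystem-average TEF (meta-analysis across food webs); tissue-independent."""
    return TEFSpec("Post", tef_tissue_for(tissue) if tissue in ("vibrissae", "lanugo") else tissue,
                   d13C_mean=0.4, d13C_sd=1.3, d15N_mean=3.4, d15N_sd=0.98)


def sider_tef(tissue: str) -> TEFSpec:
    """Phylogenetic meta-analytic TEF estimate (SIDER); tissue-independent."""
    return TEFSpec("SIDER", tef_tissue_for(tissue) if tissue in ("vibrissae", "lanugo") else tissue,
                   d13C_mean=2.4, d13C_sd=1.3, d15N_mean=2.6, d15N_sd=1.2)


def experimental_tef(tissue: str) -> TEFSpec:
    """Pooled mean ± SD of the experimentally determined phocid TEFs for a tissue."""
    tt = tef_tissue_for(tissue) if tissue in ("vibrissae", "lanugo") else tissue
    entries = [e for e in EXPERIMENTAL_TEF_ENTRIES if e.tissue == tt]
    avg = average_tefs(entries)
    return TEFSpec("Experimental", avg.tissue, avg.d13C_mean, avg.d13C_sd,
                   avg.d15N_mean, avg.d15N_sd, avg.n)


def tef_candidates(tissue: str) -> dict[str, TEFSpec]:
    """The three TEF candidates evaluated by the mixing-polygon simulation."""
    return {
        "Post": post_tef(tissue),
        "SIDER": sider_tef(tissue),
        "Experimental": experimental_tef(tissue),
    }


#: Gray seal pup tissue summaries: tissue -> sex -> (n, δ13C mean, δ13C SD,
#: δ15N mean, δ15N SD).  "all" includes one pup of unknown sex.
CONSUMER_MOMENTS: dict[str, dict[str, tuple[int, float, float, float, float]]] = {
    "vibrissae": {
        "M": (13, -16.3, 1.6, 15.4, 0.9),
        "F": (11, -16.4, 1.4, 15.2, 0.7),
        "all": (25, -16.4, 1.5, 15.3, 0.8),
    },
    "lanugo": {
        "M": (9, -16.4, 1.6, 15.6, 1.2),
        "F": (9, -16.6, 1.5, 15.6, 0.9),
        "all": (19, -16.6, 1.5, 15.6, 1.0),
    },
}

#: Scat hard-part analysis diet proportions (percent) used as an informative
#: Dirichlet prior over the three-source grouping.
SCAT_PRIOR_WEIGHTS: dict[str, float] = {
    "squid": 1.4,
    "sand lance": 53.3,
    "demersal fishes": 40.6,
}


def prey_summaries() -> list[SpeciesSummary]:
    """Prey species isotope moments as :class:`SpeciesSummary` objects."""
    return [
        SpeciesSummary(label=lab, n=v[0], d13C_mean=v[1], d13C_sd=v[2],
                       d15N_mean=v[3], d15N_sd=v[4])
        for lab, v in PREY_SPECIES.items()
    ]


def consumer_moments(tissue: str, sex: str = "all") -> tuple[int, float, float, float, float]:
    """(n, δ13C mean, δ13C SD, δ15N mean, δ15N SD) for a pup tissue."""
    return CONSUMER_MOMENTS[tissue][sex]
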