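"""Signal and metabolite catalogues for the synthetic tissue cohorts.

Each metabolite is described by one or more NMR signals (chemical shift,
multiplicity, proton count, J spacing), a standard-chow mean concentration
in mM-equivalents, a within-group coefficient of variation, and a target
standardized mean difference (high-fat vs standard-chow) injected by the
cohort simulator.

The default aqueous library covers the assignments routinely seen in
heart/kidney/muscle polar extracts (lactate, alanine, taurine, creatine,
the methylamines TMA/DMA/TMAO, malonate, glycine, GPC, uracil, glucose, …);
the default lipophilic library covers the fatty-acyl envelope (terminal
CH3, omega-3 CH3, (CH2)n, allylic, bis-allylic, glyceride and headgroup
signals). Effect sizes on selected signals default to the group differences
the simulator is meant to emulate (e.g. a strong TMA decrease and linoleic /
allylic-PUFA increases under high-fat feeding).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "SignalSpec",
    "MetaboliteSpec",
    "build_default_library",
    "chain_class_concentrations",
]

MULTIPLICITIES = ("s", "d", "t", "q", "m")

# Pascal-triangle intensity fractions for first-order multiplets.
_MULTIPLET_WEIGHTS = {
    "s": (1.0,),
    "d": (0.5, 0.5),
    "t": (0.25, 0.5, 0.25),
    "q": (0.125, 0.375, 0.375, 0.125),
    # 'm' rendered as a single unresolved broad line (handled by the simulator)
    "m": (1.0,),
}

#: default 3J(H,H) coupling, 7.3 Hz at 500.13 MHz
DEFAULT_J_PPM = 0.0146


@dataclass(frozen=True)
class SignalSpec:
    """One resonance: position, multiplicity, proton count, line spacing."""

    metabolite_name: str
    center_ppm: float
    multiplicity: str = "s"
    n_protons: int = 1
    j_spacing_ppm: float = 0.0

    def __post_init__(self) -> None:
        if self.multiplicity not in MULTIPLICITIES:
            raise ValueError(f"unknown multiplicity {self.multiplicity!r}")
        if self.n_protons < 1:
            raise ValueError("n_protons must be >= 1")
        if self.j_spacing_ppm < 0:
            raise ValueError("j_spacing_ppm must be non-negative")
        if self.multiplicity == "s" and self.j_spacing_ppm != 0:
            raise ValueError("singlet must have j_spacing_ppm == 0")

    @property
    def line_offsets_weights(self) -> list[tuple[float, float]]:
        """(offset_ppm, fraction) for each multiplet line, centred on 0."""
        w = _MULTIPLET_WEIGHTS[self.multiplicity]
        k = len(w)
        return [(self.j_spacing_ppm * (i - (k - 1) / 2), w[i]) for i in range(k)]


@dataclass(frozen=True)
class MetaboliteSpec:
    """A metabolite with its signals and cohort-level generative parameters.

    ``effect_size`` is the population standardized mean difference
    (HF − SC)/s_pooled targeted by the simulator; ``cv_within_group`` the
    fractional within-group coefficient of variation of concentration.
    """

    name: str
    signals: tuple[SignalSpec, ...]
    mean_conc_SC: float = 1.0
    effect_size: float = 0.0
    cv_within_group: float = 0.25

    def __post_init__(self) -> None:
        if self.mean_conc_SC <= 0:
            raise ValueError("mean_conc_SC must be > 0")
        if not 0 < self.cv_within_group < 1:
            raise ValueError("cv_within_group must lie in (0, 1)")
        if not self.signals:
            raise ValueError("metabolite needs at least one signal")


def _met(
    name: str,
    sigs: list[tuple[float, str, int]],
    conc: float,
    es: float = 0.0,
    cv: float = 0.25,
) -> MetaboliteSpec:
    specs = tuple(
        SignalSpec(
            name,
            ppm,
            mult,
            nH,
            0.0 if mult in ("s", "m") else DEFAULT_J_PPM,
        )
        for ppm, mult, nH in sigs
    )
    return MetaboliteSpec(name, specs, conc, es, cv)


def _aqueous_library() -> list[MetaboliteSpec]:
    # Mean concentrations are plausible tissue-extract levels (mM-equivalents
    # in the NMR tube); effect sizes follow the high-fat-diet kidney pattern:
    # decreased alanine/succinate/methionine/DMA/TMA/malonate/glycine, raised
    # pyruvate/GPC/uracil.
    return [
        _met("lactate", [(1.33, "d", 3)], 8.0),
        _met("alanine", [(1.48, "d", 3)], 2.0, es=-1.40),
        _met("methionine", [(2.13, "s", 3)], 0.4, es=-1.45),
        _met("pyruvate", [(2.37, "s", 3)], 0.4, es=1.02),
        _met("succinate", [(2.40, "s", 4)], 0.6, es=-1.01),
        _met("dimethylamine", [(2.72, "s", 6)], 0.15, es=-1.27),
        _met("trimethylamine", [(2.89, "s", 9)], 0.10, es=-2.09),
        _met("creatine", [(3.03, "s", 3), (3.93, "s", 2)], 6.0),
        _met("malonate", [(3.11, "s", 2)], 0.3, es=-1.36),
        _met("o-acetylcarnitine", [(3.19, "s", 3)], 0.3, es=-0.99),
        _met("trimethylamine-N-oxide", [(3.26, "s", 9)], 0.4),
        # taurine: N-CH2 at 3.42 and S-CH2 at 3.26 (overlapping TMAO)
        _met("taurine", [(3.26, "t", 2), (3.42, "t", 2)], 12.0),
        _met("glycine", [(3.56, "s", 2)], 2.0, es=-1.32),
        _met("glycerophosphocholine", [(4.33, "m", 1)], 1.2, es=1.05),
        # alpha-glucose: anomeric H1 doublet plus one ring proton in the
        # 3.22-3.30 region (H2), used by the TMAO overlap model
        _met("glucose", [(5.23, "d", 1), (3.24, "m", 1)], 3.0),
        _met("uracil", [(5.80, "d", 1)], 0.2, es=0.87),
        _met("U_6.80", [(6.80, "s", 1)], 0.15, es=-1.50),
    ]


def _lipophilic_library() -> list[MetaboliteSpec]:
    # Signal-level pseudo-metabolites of the fatty-acyl envelope; mean
    # concentrations approximate a tissue extract with ~24 mM total chains.
    return [
        _met("cholesterol", [(0.68, "s", 3)], 2.0),
        _met("FA_CH3", [(0.88, "t", 3)], 23.0),
        _met("omega3_CH3", [(0.97, "t", 3)], 1.0),
        _met("FA_(CH2)n", [(1.28, "m", 20)], 24.0),
        _met("FA_beta_CH2", [(1.58, "m", 2)], 24.0),
        _met("MUFA_allylic", [(2.00, "m", 4)], 12.0, es=-0.98),
        _met("PUFA_allylic", [(2.04, "m", 4)], 5.0, es=2.64),
        _met("FA_alpha_CH2", [(2.28, "m", 2)], 24.0),
        _met("linoleic_bis_allylic", [(2.76, "t", 2)], 3.0, es=2.37),
        _met("PUFA_bis_allylic", [(2.80, "m", 2)], 2.0),
        _met("PC_LPC_headgroup", [(3.30, "s", 9)], 3.0),
        _met("TG_sn1_sn3", [(4.28, "m", 4)], 2.0),
        _met("TG_sn2", [(5.21, "m", 1)], 2.0),
        _met("UFA_olefinic", [(5.33, "m", 2)], 17.0, es=1.27),
    ]


def build_default_library(phase: str) -> list[MetaboliteSpec]:
    """Return the default metabolite library for ``aqueous`` or ``lipophilic``."""
    if phase == "aqueous":
        return _aqueous_library()
    if phase == "lipophilic":
        return _lipophilic_library()
    raise ValueError(f"unknown phase {phase!r}: expected 'aqueous' or 'lipophilic'")


def chain_class_concentrations(
    sfa_mM: float,
    mufa_mM: float,
    pufa_mM: float,
    omega3_mM: float = 0.0,
    linoleic_fraction: float = 0.6,
) -> dict[str, float]:
    """Map fatty-acid chain-class concentrations to lipophilic signal levels.

    Builds a self-consistent concentration map for the lipophilic library
    from chain-class totals (mM of chains): every chain contributes one
    terminal CH3 (omega-3 chains at 0.97 ppm, the rest at 0.88 ppm), every
    unsaturated chain 4 allylic protons, every polyunsaturated chain one
    bis-allylic CH2 (split between the linoleic 2.76 ppm triplet and the
    2.80 ppm envelope). Omega-3 chains are treated as polyunsaturated, so
    omega3_mM must not exceed pufa_mM.
    """
    if min(sfa_mM, mufa_mM, pufa_mM, omega3_mM) < 0:
        raise ValueError("chain-class concentrations must be non-negative")
    if omega3_mM > pufa_mM:
        raise ValueError("omega-3 chains are a subset of PUFA chains")
    total = sfa_mM + mufa_mM + pufa_mM
    return {
        "FA_CH3": total - omega3_mM,
        "omega3_CH3": omega3_mM,
        "FA_(CH2)n": total,
        "FA_beta_CH2": total,
        "FA_alpha_CH2": total,
        "MUFA_allylic": mufa_mM,
        "PUFA_allylic": pufa_mM,
        "linoleic_bis_allylic": pufa_mM * linoleic_fraction,
        "PUFA_bis_allylic": pufa_mM * (1.0 - linoleic_fraction),
        "UFA_olefinic": mufa_mM + 2.0 * pufa_mM,
    }
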