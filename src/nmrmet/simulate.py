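"""Synthetic two-group 1D ^1H NMR cohorts with known ground truth.

The simulator emulates processed tissue-extract spectra at 500.13 MHz over a
14 ppm spectral window (7002.801 Hz): each metabolite signal is rendered as
a first-order multiplet of Lorentzian lines (area-normalised, so the
integral of a resonance equals concentration × proton count), a chemical
shift reference compound is added (TSP at δ 0.0 for aqueous extracts,
pyrazine at δ 8.6 for lipophilic ones), per-sample peak-position jitter
mimics pH/matrix shift variability, and Gaussian baseline noise is scaled
to the strongest signal.

Group differences are injected on the arithmetic scale: per-sample
concentrations are log-normal within group, and the high-fat group mean is
shifted so that the population standardized mean difference
(HF − SC)/s_pooled equals each metabolite's target effect size exactly
(see :func:`effect_size_mean_ratio` for the closed form).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .signals import MetaboliteSpec, SignalSpec, chain_class_concentrations
from .spectrum import Spectrum1D, write_spectrum

__all__ = [
    "CohortDesign",
    "GroundTruth",
    "simulate_spectrum",
    "simulate_cohort",
    "effect_size_mean_ratio",
    "write_cohort",
]

log = logging.getLogger(__name__)

#: default chemical-shift / concentration references per phase
TSP = SignalSpec("TSP", 0.0, "s", 9)
PYRAZINE = SignalSpec("pyrazine", 8.6, "s", 4)
REFERENCE_CONC_MM = {"TSP": 0.1, "pyrazine": 0.24}


@dataclass
class CohortDesign:
    """Study design and instrument model for one simulated cohort."""

    phase: str = "aqueous"
    n_SC: int = 12
    n_HF: int = 11
    tissue: str = "kidney"
    ppm_min: float = -0.5
    ppm_max: float = 13.5
    n_points: int = 16384
    linewidth_ppm: float = 0.002
    noise_sd: float = 2e-5           # fraction of the tallest clean signal
    jitter_sd_ppm: float = 0.003     # per-sample peak displacement SD
    tissue_weight_g: float = 0.15
    sample_volume_L: float = 6.0e-4  # 600 uL resuspension volume
    reference_spec: SignalSpec | None = None
    reference_conc_mM: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phase not in ("aqueous", "lipophilic"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.n_points < 1024:
            raise ValueError("n_points must be >= 1024")
        if not self.jitter_sd_ppm < 0.02:
            raise ValueError("jitter_sd_ppm must be < 0.02")
        if min(self.n_SC, self.n_HF) < 3:
            raise ValueError("group sizes must be >= 3")
        if self.tissue_weight_g <= 0:
            raise ValueError("tissue_weight_g must be positive")
        if self.reference_spec is None:
            self.reference_spec = TSP if self.phase == "aqueous" else PYRAZINE
        if self.reference_conc_mM is None:
            self.reference_conc_mM = REFERENCE_CONC_MM[self.reference_spec.metabolite_name]

    @property
    def axis(self) -> np.ndarray:
        """Descending ppm axis."""
        return np.linspace(self.ppm_max, self.ppm_min, self.n_points)


@dataclass
class GroundTruth:
    """True per-sample quantities recorded by the simulator."""

    concentrations: pd.DataFrame        # samples x metabolites, mM-equivalents
    groups: pd.Series                   # sample -> SC/HF
    weights_g: pd.Series                # sample -> tissue wet weight
    target_effect_sizes: pd.Series      # metabolite -> injected population ES
    lipid_fractions: pd.DataFrame | None = None   # %SFA/%MUFA/%PUFA/%omega3
    total_fa_umol_g: pd.Series | None = None
    methylamines_umol_g: pd.DataFrame | None = None  # TMA/DMA/TMAO per sample

    def empirical_effect_sizes(self) -> pd.Series:
        """Pooled-SD standardized mean differences (HF − SC) of the true levels."""
        sc = self.concentrations[self.groups == "SC"]
        hf = self.concentrations[self.groups == "HF"]
        n1, n2 = len(sc), len(hf)
        sp = np.sqrt(
            ((n1 - 1) * sc.var(ddof=1) + (n2 - 1) * hf.var(ddof=1)) / (n1 + n2 - 2)
        )
        return (hf.mean() - sc.mean()) / sp


def effect_size_mean_ratio(effect_size: float, cv: float) -> float:
    """HF/SC arithmetic-mean ratio giving a target standardized difference.

    With within-group SD proportional to the mean (SD = cv × mean) the pooled
    SD is cv·sqrt((1 + r²)/2) times the SC mean, so the standardized
    difference d satisfies r − 1 = d·cv·sqrt((1 + r²)/2). Writing
    a = 1 − (d·cv)²/2 the positive solution is r = (1 ± sqrt(1 − a²))/a with
    the sign of d, which this function returns exactly (no first-order
    approximation needed).
    """
    d = effect_size * cv
    a = 1.0 - d * d / 2.0
    if a <= 0:
        raise ValueError(
            f"|effect_size|*cv = {abs(d):.3f} >= sqrt(2): no positive mean ratio exists"
        )
    root = np.sqrt(max(0.0, 1.0 - a * a))
    r = (1.0 + np.sign(d) * root) / a
    return float(r)


def _render_signal(
    axis: np.ndarray,
    sig: SignalSpec,
    conc: float,
    linewidth: float,
    center_shift: float = 0.0,
) -> np.ndarray:
    """Area-normalised Lorentzian multiplet: integral = conc × n_protons."""
    gamma = linewidth * (2.0 if sig.multiplicity == "m" else 1.0)
    out = np.zeros_like(axis)
    for offset, weight in sig.line_offsets_weights:
        x0 = sig.center_ppm + center_shift + offset
        out += weight * gamma / (np.pi * (gamma**2 + (axis - x0) ** 2))
    return conc * sig.n_protons * out


def simulate_spectrum(
    design: CohortDesign,
    library: list[MetaboliteSpec],
    concentrations: dict[str, float],
    sample_seed: int,
    meta: dict | None = None,
) -> Spectrum1D:
    """Render one spectrum for the given per-metabolite concentration map.

    Jitter (one displacement per metabolite, shared by its signals) and
    baseline noise are drawn from ``sample_seed``; identical inputs give
    bit-identical output.
    """
    for name, c in concentrations.items():
        if c < 0:
            raise ValueError(f"negative concentration for {name!r}: {c}")
    axis = design.axis
    step = (design.ppm_max - design.ppm_min) / (design.n_points - 1)
    rng = np.random.default_rng(sample_seed)
    clean = np.zeros_like(axis)
    for met in library:
        conc = concentrations.get(met.name, 0.0)
        jitter = rng.normal(0.0, design.jitter_sd_ppm) if design.jitter_sd_ppm > 0 else 0.0
        if conc == 0.0:
            continue
        for sig in met.signals:
            if sig.j_spacing_ppm > 0 and sig.j_spacing_ppm < 2 * step:
                log.warning(
                    "axis too coarse to resolve J=%.4f ppm for %s", sig.j_spacing_ppm, met.name
                )
            clean += _render_signal(axis, sig, conc, design.linewidth_ppm, jitter)
    clean += _render_signal(
        axis, design.reference_spec, design.reference_conc_mM, design.linewidth_ppm
    )
    noise_scale = design.noise_sd * clean.max()
    intensity = clean + (rng.normal(0.0, noise_scale, axis.size) if noise_scale > 0 else 0.0)
    md = {
        "tissue": design.tissue,
        "phase": design.phase,
        "weight_g": design.tissue_weight_g,
        "fully_relaxed": True,
        **(meta or {}),
    }
    return Spectrum1D(axis, intensity, md)


def _draw_lognormal(mean: float, cv: float, rng: np.random.Generator) -> float:
    sigma = np.sqrt(np.log1p(cv**2))
    mu = np.log(mean) - sigma**2 / 2.0
    return float(rng.lognormal(mu, sigma))


def _group_mean(met: MetaboliteSpec, group: str, mean: float | None = None) -> float:
    mean = met.mean_conc_SC if mean is None else mean
    if group == "HF" and met.effect_size != 0.0:
        mean *= effect_size_mean_ratio(met.effect_size, met.cv_within_group)
    return mean


#: fatty-acyl signals derived from the latent chain classes (lipophilic phase)
_FA_SIGNAL_NAMES = frozenset(chain_class_concentrations(1, 1, 1, 0.5))


def _draw_concentrations(
    library: list[MetaboliteSpec], group: str, rng: np.random.Generator,
    phase: str = "aqueous",
) -> dict[str, float]:
    by_name = {m.name: m for m in library}
    out: dict[str, float] = {}
    use_chain_model = phase == "lipophilic" and _FA_SIGNAL_NAMES <= set(by_name)
    if use_chain_model:
        # Fatty-acyl signals share chains, so they are derived from latent
        # chain-class draws instead of independent ones: a real extract can
        # never show more unsaturated than total chains. Group shifts ride on
        # the allylic signals' effect sizes (MUFA and PUFA respectively).
        mufa_met = by_name["MUFA_allylic"]
        pufa_met = by_name["PUFA_allylic"]
        ch3 = by_name["FA_CH3"]
        omega3_met = by_name["omega3_CH3"]
        mufa_mean = _group_mean(mufa_met, group)
        pufa_mean = _group_mean(pufa_met, group)
        sfa_mean = max(
            ch3.mean_conc_SC + omega3_met.mean_conc_SC
            - mufa_met.mean_conc_SC - pufa_met.mean_conc_SC,
            0.05 * ch3.mean_conc_SC,
        )
        mufa = _draw_lognormal(mufa_mean, mufa_met.cv_within_group, rng)
        pufa = _draw_lognormal(pufa_mean, pufa_met.cv_within_group, rng)
        sfa = _draw_lognormal(sfa_mean, ch3.cv_within_group, rng)
        omega3_frac = omega3_met.mean_conc_SC / pufa_met.mean_conc_SC
        lin = by_name["linoleic_bis_allylic"].mean_conc_SC
        lin_frac = lin / (lin + by_name["PUFA_bis_allylic"].mean_conc_SC)
        out.update(
            chain_class_concentrations(
                sfa, mufa, pufa,
                omega3_mM=min(omega3_frac, 1.0) * pufa,
                linoleic_fraction=lin_frac,
            )
        )
    for met in library:
        if met.name in out:
            continue
        out[met.name] = _draw_lognormal(
            _group_mean(met, group), met.cv_within_group, rng
        )
    return out


def simulate_cohort(
    design: CohortDesign,
    library: list[MetaboliteSpec],
    seed: int | None = None,
) -> tuple[list[Spectrum1D], GroundTruth]:
    """Simulate a labelled SC/HF cohort and record its ground truth."""
    if not library:
        raise ValueError("library must be nonempty")
    if min(design.n_SC, design.n_HF) < 3:
        raise ValueError("group sizes must be >= 3 for downstream statistics")
    seed = design.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    conc_rng = np.random.default_rng(ss.spawn(1)[0])
    sample_seeds = np.random.default_rng(ss).integers(0, 2**31 - 1, design.n_SC + design.n_HF)

    spectra: list[Spectrum1D] = []
    rows = []
    ids, groups, weights = [], [], []
    labels = [("SC", i + 1) for i in range(design.n_SC)] + [
        ("HF", i + 1) for i in range(design.n_HF)
    ]
    for k, (group, idx) in enumerate(labels):
        sid = f"{group}{idx:02d}"
        conc = _draw_concentrations(library, group, conc_rng, design.phase)
        s = simulate_spectrum(
            design, library, conc, int(sample_seeds[k]),
            meta={"sample_id": sid, "group": group},
        )
        spectra.append(s)
        rows.append(conc)
        ids.append(sid)
        groups.append(group)
        weights.append(design.tissue_weight_g)

    conc_df = pd.DataFrame(rows, index=pd.Index(ids, name="sample_id"))
    groups_s = pd.Series(groups, index=conc_df.index, name="group")
    weights_s = pd.Series(weights, index=conc_df.index, name="weight_g")
    target_es = pd.Series({m.name: m.effect_size for m in library}, name="effect_size")

    gt = GroundTruth(conc_df, groups_s, weights_s, target_es)
    _attach_truth_profiles(gt, design, library)
    return spectra, gt


def _attach_truth_profiles(
    gt: GroundTruth, design: CohortDesign, library: list[MetaboliteSpec]
) -> None:
    """Fill phase-specific true quantitative profiles where derivable."""
    conc = gt.concentrations
    to_umol_g = design.sample_volume_L * 1e3 / design.tissue_weight_g  # mM -> umol/g
    if design.phase == "aqueous":
        name_map = {
            "TMA": "trimethylamine",
            "DMA": "dimethylamine",
            "TMAO": "trimethylamine-N-oxide",
        }
        present = {k: v for k, v in name_map.items() if v in conc.columns}
        if present:
            gt.methylamines_umol_g = pd.DataFrame(
                {k: conc[v] * to_umol_g for k, v in present.items()}
            )
    else:
        needed = {"FA_CH3", "omega3_CH3", "MUFA_allylic", "PUFA_allylic"}
        if needed <= set(conc.columns):
            chains = conc["FA_CH3"] + conc["omega3_CH3"]
            mufa = conc["MUFA_allylic"]
            pufa = conc["PUFA_allylic"]
            sfa = (chains - mufa - pufa).clip(lower=0.0)
            gt.lipid_fractions = pd.DataFrame(
                {
                    "pct_SFA": 100.0 * sfa / chains,
                    "pct_MUFA": 100.0 * mufa / chains,
                    "pct_PUFA": 100.0 * pufa / chains,
                    "pct_omega3": 100.0 * conc["omega3_CH3"] / chains,
                }
            )
            gt.total_fa_umol_g = (chains * to_umol_g).rename("total_FA_umol_g")


def write_cohort(
    spectra: list[Spectrum1D], gt: GroundTruth, out_dir: str | Path
) -> pd.DataFrame:
    """Write spectra (two-column text), metadata and ground-truth tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in spectra:
        sid = s.meta["sample_id"]
        fname = f"{sid}_{s.meta['phase']}.txt"
        write_spectrum(s, out / fname)
        rows.append(
            {
                "sample_id": sid,
                "tissue": s.meta["tissue"],
                "group": s.meta["group"],
                "phase": s.meta["phase"],
                "weight_g": s.meta["weight_g"],
                "file": fname,
            }
        )
    meta_df = pd.DataFrame(rows).set_index("sample_id")
    meta_df.to_csv(out / "samples.tsv", sep="\t")
    gt.concentrations.to_csv(out / "ground_truth_concentrations.tsv", sep="\t")
    return meta_df
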