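"""Synthetic LIBS spectra with the study's sampling design.

The generator emulates the experiment this package was built to analyse:
eight commercial brands of *Fritillaria thunbergii* powder, each split into
eight concentration-gradient groups spiked with cadmium / copper / lead
nitrate solutions, three replicate pellets per group — 192 spectra of 1024
channels over 210–231 nm.

Each spectrum is a smooth polynomial continuum plus Gaussian emission lines
at the NIST wavelengths of the analytes (line height proportional to
concentration), plus fixed "matrix" lines from the plant material itself,
distorted by per-sample multiplicative/additive scatter and shot noise.
The spike-volume arithmetic of the wet-lab protocol is reproduced exactly
so that the gradient levels are traceable to pipetted volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .spectra_core import ELEMENTS, SampleMeta, SpectraSet, SpectralAxis

#: molar masses (g/mol) as rounded in the wet-lab arithmetic; exact IUPAC
#: values available via ``build_gradient_plan(..., exact_masses=True)``
MOLAR_MASS = {"Cd": 112.4, "Cu": 64.0, "Pb": 207.2}
MOLAR_MASS_IUPAC = {"Cd": 112.414, "Cu": 63.546, "Pb": 207.2}

#: spiking gradient targets, mg/kg, per element (group 1 is the unspiked control)
GRADIENT_LEVELS = {
    "Cd": (0.0, 5.0, 10.0, 20.0, 25.0, 50.0, 80.0, 100.0),
    "Cu": (0.0, 20.0, 40.0, 60.0, 80.0, 100.0, 200.0, 300.0),
    "Pb": (0.0, 5.0, 20.0, 40.0, 60.0, 80.0, 100.0, 200.0),
}


@dataclass(frozen=True)
class EmissionLine:
    """One atomic emission line: element, ionization stage, center (nm), strength."""

    element: str
    stage: str  # "I" neutral, "II" singly ionized
    center: float
    relative_strength: float = 1.0

    def __post_init__(self):
        if not (210.0 <= self.center <= 231.0):
            raise ValueError(f"line center {self.center} nm outside [210, 231] nm")
        if self.relative_strength <= 0:
            raise ValueError("relative_strength must be > 0")


#: analyte lines identified in the 210–231 nm window (NIST ASD)
DEFAULT_LINES = (
    EmissionLine("Cd", "II", 214.44, 0.85),
    EmissionLine("Cd", "II", 226.50, 0.75),
    EmissionLine("Cd", "I", 228.80, 1.00),
    EmissionLine("Cu", "II", 217.94, 1.00),
    EmissionLine("Cu", "II", 222.89, 0.65),
    EmissionLine("Cu", "II", 224.26, 0.55),
    EmissionLine("Pb", "I", 217.00, 1.00),
    EmissionLine("Pb", "II", 220.35, 0.70),
)

#: decoy matrix lines (center nm, absolute peak intensity) not tied to analytes
DEFAULT_MATRIX_LINES = (
    (211.50, 900.0),
    (213.20, 500.0),
    (216.20, 1400.0),
    (219.30, 700.0),
    (223.60, 1100.0),
    (229.90, 600.0),
)


@dataclass(frozen=True)
class SpikePlan:
    """Gradient levels for one element and the spike volumes that realize them."""

    element: str
    molar_mass: float  # g/mol
    molarity: float  # mol/L
    sample_mass: float  # g
    levels: tuple  # mg/kg
    volumes: tuple  # µL

    def __post_init__(self):
        if len(self.volumes) != len(self.levels):
            raise ValueError("volumes and levels must have equal length")
        if self.levels and self.levels[0] == 0 and self.volumes[0] != 0:
            raise ValueError("volume must be 0 at level 0")
        if any(b <= a for a, b in zip(self.volumes, self.volumes[1:])):
            raise ValueError("volumes must be strictly increasing with level")


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic-spectrum generator.

    Defaults encode the study design: (8 brands, 8 groups, 3 replicates),
    analyte lines above, Gaussian line profile sigma 0.06 nm, a gently
    sloping continuum, ~10% lognormal multiplicative scatter plus an
    additive offset, and unspiked brand backgrounds with medians matching
    the control-group reference measurements (Cd 0.4, Cu 3, Pb 0.3 mg/kg).
    """

    design: tuple = (8, 8, 3)  # (n_brands, n_groups, n_replicates)
    n_channels: int = 1024
    wl_range: tuple = (210.0, 231.0)
    lines: tuple = DEFAULT_LINES
    sensitivity: dict = field(
        default_factory=lambda: {"Cd": 8.0, "Cu": 4.0, "Pb": 5.5}
    )  # intensity units per mg/kg at a strength-1.0 line; top gradient
    # levels peak near the matrix-line scale (~800-1200 units) — trace
    # analyte lines ride on, not dominate, the emission
    peak_sigma: float = 0.06  # nm (~3-channel FWHM on the 1024-point axis)
    baseline_coeffs: tuple = (250.0, 120.0, -80.0)  # polynomial in u=(λ-210)/21
    brand_effect_sd: float = 0.05  # per-brand multiplicative lognormal sigma
    scatter_sigma: float = 0.1  # per-sample multiplicative lognormal sigma
    scatter_offset_frac: float = 0.02  # additive offset sd, fraction of median intensity
    matrix_line_sigma: float = 0.12  # per-sample lognormal jitter of each matrix line
    baseline_jitter: float = 0.06  # per-sample fractional sd on baseline coefficients
    noise_sd: float = 5.0  # additive per-channel noise of the 18-shot-averaged spectrum
    matrix_lines: tuple = DEFAULT_MATRIX_LINES
    background_median: dict = field(
        default_factory=lambda: {"Cd": 0.4, "Cu": 3.0, "Pb": 0.3}
    )  # unspiked content, mg/kg
    background_sigma: float = 0.5  # lognormal sigma of brand backgrounds
    replicate_conc_sigma: float = 0.04  # lognormal jitter of per-pellet content
    saturation_K: float | None = None  # mg/kg; None = linear response
    seed: int = 0

    def __post_init__(self):
        if any(n < 1 for n in self.design):
            raise ValueError("design entries must be >= 1")
        for name in ("brand_effect_sd", "scatter_sigma", "scatter_offset_frac", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(s <= 0 for s in self.sensitivity.values()):
            raise ValueError("sensitivities must be > 0")

    def axis(self) -> SpectralAxis:
        return SpectralAxis(np.linspace(*self.wl_range, self.n_channels))

    def scatter_enabled(self) -> bool:
        return self.scatter_sigma > 0 or self.scatter_offset_frac > 0


def spike_volume(target_conc: float, sample_mass: float, molarity: float, molar_mass: float) -> float:
    """Volume (µL) of spiking solution bringing ``sample_mass`` g of powder
    to ``target_conc`` mg/kg of the analyte.

    mg/kg x g = µg of analyte; dividing by molar mass gives µmol, and a
    ``molarity`` mol/L solution carries ``molarity`` µmol per µL x 10^-3,
    so V = c·m / (M·C) µL. Exact arithmetic; rounding is display-only.
    """
    if molarity <= 0 or molar_mass <= 0:
        raise ValueError("molarity and molar_mass must be > 0")
    if target_conc < 0 or sample_mass < 0:
        raise ValueError("target_conc and sample_mass must be >= 0")
    return target_conc * sample_mass / (molar_mass * molarity)


def build_gradient_plan(element: str, *, molarity: float = 0.01, sample_mass: float = 5.0,
                        exact_masses: bool = False) -> SpikePlan:
    """The study's spiking gradient for one element, volumes derived from levels."""
    if element not in ELEMENTS:
        raise KeyError(f"unknown element {element!r}; expected one of {ELEMENTS}")
    mass = (MOLAR_MASS_IUPAC if exact_masses else MOLAR_MASS)[element]
    levels = GRADIENT_LEVELS[element]
    volumes = tuple(spike_volume(c, sample_mass, molarity, mass) for c in levels)
    return SpikePlan(element, mass, molarity, sample_mass, levels, volumes)


def _gaussian_profile(wl: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def _clean_spectrum(conc: dict, cfg: GeneratorConfig, wl: np.ndarray,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Continuum + analyte lines + matrix lines.

    When ``rng`` is given, the continuum coefficients and matrix-line
    strengths jitter per sample — the correlated shot-to-shot plasma and
    matrix variability that dominates the covariance of real averaged
    LIBS spectra (and is what makes a handful of principal components
    carry most of the variance).
    """
    u = (wl - cfg.wl_range[0]) / (cfg.wl_range[1] - cfg.wl_range[0])
    coeffs = np.asarray(cfg.baseline_coeffs, dtype=float)
    if rng is not None and cfg.baseline_jitter > 0:
        coeffs = coeffs * (1.0 + rng.normal(0.0, cfg.baseline_jitter, size=coeffs.size))
    y = np.polynomial.polynomial.polyval(u, coeffs)
    for line in cfg.lines:
        c = conc.get(line.element, 0.0)
        if c < 0:
            raise ValueError(f"negative concentration for {line.element}")
        g = c if cfg.saturation_K is None else c / (1.0 + c / cfg.saturation_K)
        height = line.relative_strength * cfg.sensitivity[line.element] * g
        if height:
            y = y + height * _gaussian_profile(wl, line.center, cfg.peak_sigma)
    for center, strength in cfg.matrix_lines:
        if rng is not None and cfg.matrix_line_sigma > 0:
            strength = strength * rng.lognormal(0.0, cfg.matrix_line_sigma)
        y = y + strength * _gaussian_profile(wl, center, cfg.peak_sigma)
    return y


def generate_spectrum(conc: dict, cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """One spectrum for given analyte concentrations (mg/kg).

    intensity(λ) = m·[baseline + analyte lines + matrix lines] + offset + ε,
    with m lognormal, offset and ε Gaussian, and per-sample jitter of the
    baseline/matrix-line terms; clipped at 0.
    """
    wl = cfg.axis().wavelengths
    y = _clean_spectrum(conc, cfg, wl, rng)
    if cfg.scatter_sigma > 0:
        y = y * rng.lognormal(0.0, cfg.scatter_sigma)
    if cfg.scatter_offset_frac > 0:
        y = y + rng.normal(0.0, cfg.scatter_offset_frac * np.median(y))
    if cfg.noise_sd > 0:
        y = y + rng.normal(0.0, cfg.noise_sd, size=wl.size)
    return np.clip(y, 0.0, None)


def generate_dataset(cfg: GeneratorConfig | None = None) -> SpectraSet:
    """The full synthetic experiment: one spectrum per (brand, group, replicate).

    Per-group target concentrations follow the three spiking gradients; each
    brand adds a small lognormal unspiked background drawn once per brand,
    and each pellet's realized content jitters around the target (emulating
    the spread of the reference ICP-MS measurements). The recorded reference
    concentration is the realized content the spectrum was generated from.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    n_brands, n_groups, n_reps = cfg.design
    plans = {el: build_gradient_plan(el) for el in ELEMENTS}

    backgrounds = {
        b: {
            el: cfg.background_median[el] * rng.lognormal(0.0, cfg.background_sigma)
            for el in ELEMENTS
        }
        for b in range(1, n_brands + 1)
    }
    brand_factor = {
        b: rng.lognormal(0.0, cfg.brand_effect_sd) if cfg.brand_effect_sd > 0 else 1.0
        for b in range(1, n_brands + 1)
    }

    axis = cfg.axis()
    rows, metas = [], []
    for b in range(1, n_brands + 1):
        for g in range(1, n_groups + 1):
            for r in range(1, n_reps + 1):
                conc = {}
                for el in ELEMENTS:
                    levels = plans[el].levels
                    target = levels[(g - 1) % len(levels)] + backgrounds[b][el]
                    jitter = (
                        rng.lognormal(0.0, cfg.replicate_conc_sigma)
                        if cfg.replicate_conc_sigma > 0
                        else 1.0
                    )
                    conc[el] = target * jitter
                y = generate_spectrum(conc, cfg, rng) * brand_factor[b]
                rows.append(y)
                metas.append(
                    SampleMeta(
                        sample_id=f"B{b}G{g}R{r}",
                        brand=b,
                        group=g,
                        replicate=r,
                        conc=conc,
                    )
                )
    X = np.vstack(rows) if rows else np.empty((0, axis.n_channels))
    return SpectraSet(axis, X, metas)


def noiseless_config(**overrides) -> GeneratorConfig:
    """A deterministic, scatter-free, noise-free variant (useful for oracles)."""
    base = dict(
        brand_effect_sd=0.0,
        scatter_sigma=0.0,
        scatter_offset_frac=0.0,
        matrix_line_sigma=0.0,
        baseline_jitter=0.0,
        noise_sd=0.0,
        background_sigma=0.0,
        replicate_conc_sigma=0.0,
    )
    base.update(overrides)
    return replace(GeneratorConfig(), **base)


def average_shots(spectra: list, positions: int, accumulations: int) -> np.ndarray:
    """Average per-position accumulated spectra, discarding the first position.

    The acquisition protocol fires at ``positions`` spots with
    ``accumulations`` pulses each (position-major order); the first spot is
    discarded to reduce spot-to-spot fluctuation, e.g. 7x3 shots -> mean of 18.
    """
    expected = positions * accumulations
    if len(spectra) != expected:
        raise ValueError(f"expected {expected} spectra ({positions}x{accumulations}), got {len(spectra)}")
    kept = np.asarray(spectra[accumulations:], dtype=float)
    return kept.mean(axis=0)
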