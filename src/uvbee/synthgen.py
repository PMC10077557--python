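"""Synthetic UV-Vis spectrum generator.

Emulates the study system — dilute aqueous NaCl, NaOH and beta-phenylethylamine
(PEA), plus their seven-mole-fraction mixtures — as sums of Gaussian absorption
bands obeying Beer-Lambert additivity, with optional additive instrument noise.

Default band positions follow the characteristic peaks of the three solutes
(PEA at 210 and 258 nm, NaOH at 202 nm, NaCl at 197 nm); the peak-strength
ordering at equal concentration is PEA > NaOH > NaCl. The molar-absorptivity
scales are calibrated once so that the 258 nm feature of a mixture is only
visible when the PEA mole fraction reaches about 10% m/m and so that the
weakest in-range sample still sits well above the default noise floor.

Mixture classes are the seven mole-fraction recipes (0-60% m/m PEA); each
generated sample jitters the recipe concentrations by up to +/-20%
(log-uniform) to mimic independently prepared solutions. Single-component
concentrations are drawn log-uniformly from the preparation ranges, which span
up to five orders of magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import SpectraSet, UVSpectrum, default_grid

__all__ = [
    "BandSpec",
    "ComponentModel",
    "MixtureRow",
    "MixtureDesign",
    "NoiseModel",
    "DEFAULT_COMPONENTS",
    "COMPONENT_CONC_RANGES",
    "DEFAULT_MIXTURES",
    "component_spectrum",
    "mixture_spectrum",
    "generate_dataset",
]


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band: peak center (nm), sigma width (nm) and
    molar-absorptivity scale (absorbance L/mol at the peak for unit path)."""

    center: float
    width: float
    epsilon: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass(frozen=True)
class ComponentModel:
    """A pure solute as a list of absorption bands."""

    name: str
    bands: tuple[BandSpec, ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("a component needs at least one band")


@dataclass(frozen=True)
class MixtureRow:
    """One mixture recipe: PEA mole fraction (% m/m) and molar concentrations."""

    fraction_percent: float
    nacl: float
    naoh: float
    pea: float

    def __post_init__(self) -> None:
        if min(self.nacl, self.naoh, self.pea) < 0:
            raise ValueError("concentrations must be non-negative")


@dataclass(frozen=True)
class MixtureDesign:
    """The set of mixture recipes defining the mixture classes."""

    rows: tuple[MixtureRow, ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("empty mixture design")


@dataclass
class NoiseModel:
    """Additive instrument-noise surrogate.

    ``sigma`` is i.i.d. Gaussian absorbance noise per wavelength;
    ``baseline_amplitude`` adds one slow sinusoidal drift across the grid with
    a random phase per spectrum.
    """

    sigma: float = 0.002
    baseline_amplitude: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def apply(self, absorbance: np.ndarray, grid: np.ndarray,
              rng: np.random.Generator) -> np.ndarray:
        out = np.asarray(absorbance, dtype=float).copy()
        if self.baseline_amplitude:
            phase = rng.uniform(0, 2 * np.pi)
            span = grid[-1] - grid[0]
            out += self.baseline_amplitude * np.sin(
                2 * np.pi * (grid - grid[0]) / (2 * span) + phase)
        if self.sigma:
            out += rng.normal(0.0, self.sigma, size=out.shape)
        return out


# calibrated once; see module docstring
DEFAULT_COMPONENTS: dict[str, ComponentModel] = {
    "NaCl": ComponentModel("NaCl", (BandSpec(197.0, 6.0, 2.0e4),)),
    "NaOH": ComponentModel("NaOH", (BandSpec(202.0, 6.0, 3.0e4),)),
    "PEA": ComponentModel("PEA", (BandSpec(210.0, 6.0, 6.0e4),
                                  BandSpec(258.0, 6.0, 8.0e3))),
}

# preparation ranges of the single-component dilution series (mol/L)
COMPONENT_CONC_RANGES: dict[str, tuple[float, float]] = {
    "NaCl": (3.52e-6, 0.5),
    "NaOH": (7.62e-6, 0.5),
    "PEA": (3.06e-6, 8.91e-3),
}

# the seven mole-fraction recipes (% m/m PEA; concentrations in mol/L)
DEFAULT_MIXTURES = MixtureDesign((
    MixtureRow(0, 1.24e-5, 3.92e-5, 0.0),
    MixtureRow(10, 1.54e-5, 4.09e-5, 6.25e-6),
    MixtureRow(20, 2.67e-5, 1.07e-5, 9.36e-6),
    MixtureRow(30, 3.24e-5, 7.7e-6, 1.72e-5),
    MixtureRow(40, 4.45e-5, 4.7e-6, 3.28e-5),
    MixtureRow(50, 3.15e-5, 1.5e-5, 4.65e-5),
    MixtureRow(60, 1.95e-5, 1.46e-5, 5.12e-5),
))


def component_spectrum(model: ComponentModel, concentration: float,
                       grid: np.ndarray | None = None) -> UVSpectrum:
    """Noiseless Beer-Lambert spectrum: sum of Gaussian bands scaled by
    concentration. Zero concentration gives the all-zero spectrum."""
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    absorbance = np.zeros_like(grid)
    for band in model.bands:
        absorbance += (concentration * band.epsilon *
                       np.exp(-((grid - band.center) ** 2) / (2 * band.width ** 2)))
    return UVSpectrum(grid, absorbance, model.name, float(concentration))


def mixture_spectrum(parts: list[tuple[ComponentModel, float]],
                     grid: np.ndarray | None = None,
                     label: str = "") -> UVSpectrum:
    """Pointwise sum of component spectra (Beer-Lambert additivity)."""
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    absorbance = np.zeros_like(grid)
    total = 0.0
    for model, conc in parts:
        absorbance += component_spectrum(model, conc, grid).absorbance
        total += conc
    return UVSpectrum(grid, absorbance, label, total)


def _split(spectra: list[UVSpectrum], train_fraction: float,
           rng: np.random.Generator) -> tuple[list[UVSpectrum], list[UVSpectrum]]:
    n = len(spectra)
    n_train = int(round(train_fraction * n))
    perm = rng.permutation(n)
    train = [spectra[i] for i in sorted(perm[:n_train])]
    test = [spectra[i] for i in sorted(perm[n_train:])]
    return train, test


def generate_dataset(
    design: MixtureDesign | dict[str, tuple[float, float]] | None = None,
    n_per_class: int = 30,
    noise: NoiseModel | None = None,
    train_fraction: float = 2 / 3,
    seed: int = 0,
    grid: np.ndarray | None = None,
) -> tuple[SpectraSet, SpectraSet]:
    """Generate a stratified, seeded train/test dataset.

    ``design`` is either a :class:`MixtureDesign` (mixture classes, recipe
    concentrations jittered log-uniformly by +/-20% per sample) or a mapping
    ``name -> (low, high)`` of single-component concentration ranges sampled
    log-uniformly (default: the three solutes over their preparation ranges).
    ``noise=None`` means noiseless spectra. 30 samples per class with
    ``train_fraction=2/3`` yields the canonical 20 train / 10 test split.
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    if design is None:
        design = COMPONENT_CONC_RANGES
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)

    train_all: list[UVSpectrum] = []
    test_all: list[UVSpectrum] = []

    if isinstance(design, MixtureDesign):
        class_iter = [
            (f"{row.fraction_percent:g}", row) for row in design.rows]
    else:
        if not design:
            raise ValueError("empty design")
        class_iter = [(name, design[name]) for name in design]

    for label, spec_def in class_iter:
        samples = []
        for _ in range(n_per_class):
            if isinstance(spec_def, MixtureRow):
                jitter = np.exp(rng.uniform(np.log(0.8), np.log(1.2), size=3))
                parts = [
                    (DEFAULT_COMPONENTS["NaCl"], spec_def.nacl * jitter[0]),
                    (DEFAULT_COMPONENTS["NaOH"], spec_def.naoh * jitter[1]),
                    (DEFAULT_COMPONENTS["PEA"], spec_def.pea * jitter[2]),
                ]
                s = mixture_spectrum(parts, grid, label=label)
            else:
                low, high = spec_def
                conc = float(np.exp(rng.uniform(np.log(low), np.log(high))))
                model = DEFAULT_COMPONENTS.get(
                    label, ComponentModel(label, DEFAULT_COMPONENTS["NaCl"].bands))
                s = component_spectrum(model, conc, grid)
            if noise is not None:
                s = UVSpectrum(grid.copy(),
                               noise.apply(s.absorbance, grid, rng),
                               s.label, s.concentration)
            samples.append(s)
        tr, te = _split(samples, train_fraction, rng)
        train_all.extend(tr)
        test_all.extend(te)

    return SpectraSet(train_all), SpectraSet(test_all)
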