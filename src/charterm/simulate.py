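"""Synthetic temperature-dependent MIR charcoal spectra and count tables.

A spectrum is a sum of Gaussian absorbance bands on a gentle linear baseline.
Charring temperature acts linearly on the amplitude of the
temperature-sensitive bands (anchored at the 475 degC midpoint of the 350-600
degC calibration range), so that with noise off the map T -> spectrum is
exactly affine -- the setting in which a 1-factor PLS model is exact -- while
multiplicative log-normal scatter and additive Gaussian noise emulate ATR
contact variation and detector noise.  Per-taxon presets place the
temperature-sensitive bands at the diagnostic wavenumbers identified for
olive, evergreen oak, and maritime pine charcoal, plus temperature-neutral
filler bands common to burnt organic matter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .anthraco import TaxonCountTable
from .exceptions import ValidationError
from .spectra import CalibrationSet, GridSpec, SpectralMatrix, Spectrum, stack

__all__ = [
    "BandSpec",
    "GeneratorConfig",
    "taxon_preset",
    "uninformative",
    "simulate_spectrum",
    "simulate_calibration",
    "simulate_archaeological",
    "simulate_count_table",
    "DEFAULT_TEMPERATURES",
]

log = logging.getLogger("charterm")

#: the laboratory charring grid: 350-600 degC in 50 degC steps
DEFAULT_TEMPERATURES = (350.0, 400.0, 450.0, 500.0, 550.0, 600.0)

ANCHOR_T = 475.0  # midpoint of the charring range; slopes are deviations from here


@dataclass
class BandSpec:
    """One Gaussian absorbance band; ``temp_slope`` is absorbance per degC."""

    center: float
    width: float
    base_amplitude: float
    temp_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValidationError("band width must be positive")


@dataclass
class GeneratorConfig:
    """Full description of the synthetic acquisition.

    ``scatter_sd`` is the log-scale sd of a per-spectrum multiplicative
    factor; ``noise_sd`` the sd of additive per-point noise (absorbance).
    """

    bands: list = field(default_factory=list)
    baseline_offset: float = 0.10
    baseline_slope: float = 5e-5  # absorbance per cm^-1 above the grid low end
    scatter_sd: float = 0.05
    noise_sd: float = 0.005
    grid: GridSpec = field(default_factory=GridSpec)
    taxon: str = "custom"

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.scatter_sd < 0:
            raise ValidationError("noise_sd and scatter_sd must be nonnegative")
        for b in self.bands:
            if not (self.grid.low <= b.center <= self.grid.high):
                raise ValidationError(
                    f"band center {b.center} outside the analysis window"
                )


_WIDTH = 12.0
_SLOPE = 4e-4

# base amplitudes per band center (absorbance, within 0.2-1.0)
_AMPLITUDES = {
    1730.0: 0.45, 1580.0: 0.90, 1570.0: 0.85, 1410.0: 0.60, 1380.0: 0.55,
    1370.0: 0.50, 1270.0: 0.40, 1245.0: 0.50, 1040.0: 0.80, 800.0: 0.30,
    740.0: 0.25,
}

# diagnostic (temperature-sensitive) bands per taxon with slope signs:
# carbonyl/polysaccharide/resin bands decay with charring, aromatic bands grow
_PRESETS = {
    "Olea": {1730.0: -1, 1580.0: +1, 1410.0: +1, 800.0: -1, 740.0: -1},
    "Quercus": {1580.0: +1, 1410.0: +1, 1370.0: +1, 800.0: -1, 740.0: -1, 1730.0: 0},
    "Pinus": {1730.0: -1, 1410.0: +1, 1370.0: +1, 1245.0: -1, 1040.0: -1},
}

_FILLERS = (1570.0, 1380.0, 1270.0, 1040.0)


def taxon_preset(taxon: str) -> GeneratorConfig:
    """Generator preset whose sensitive bands are a taxon's diagnostic list.

    Temperature-neutral filler bands typical of burnt organic matter (1570,
    1380, 1270, 1040 cm^-1) are added for realism wherever they do not
    coincide with a diagnostic band.
    """
    if taxon not in _PRESETS:
        raise ValidationError(f"unknown taxon {taxon!r}; choose from {sorted(_PRESETS)}")
    spec = _PRESETS[taxon]
    bands = [
        BandSpec(c, _WIDTH, _AMPLITUDES[c], sign * _SLOPE) for c, sign in spec.items()
    ]
    for c in _FILLERS:
        if c not in spec:
            bands.append(BandSpec(c, _WIDTH, _AMPLITUDES[c], 0.0))
    return GeneratorConfig(bands=bands, taxon=taxon)


def uninformative(cfg: GeneratorConfig) -> GeneratorConfig:
    """Copy of a config with every temperature slope zeroed (null spectra)."""
    return replace(cfg, bands=[replace(b, temp_slope=0.0) for b in cfg.bands])


def simulate_spectrum(T: float, cfg: GeneratorConfig, seed) -> Spectrum:
    """Draw one spectrum at charring temperature ``T`` (deterministic per seed)."""
    if not 0 <= T <= 1200:
        raise ValidationError(f"temperature {T} degC outside the sane range 0-1200")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    nu = cfg.grid.axis
    signal = cfg.baseline_offset + cfg.baseline_slope * (nu - cfg.grid.low)
    for b in cfg.bands:
        amp = b.base_amplitude + b.temp_slope * (T - ANCHOR_T)
        if amp < 0:
            log.warning("band %.0f cm^-1 amplitude %.4f < 0 at T=%.0f; floored", b.center, amp, T)
            amp = 0.0
        signal = signal + amp * np.exp(-((nu - b.center) ** 2) / (2 * b.width**2))
    m = float(np.exp(rng.normal(0.0, cfg.scatter_sd))) if cfg.scatter_sd > 0 else 1.0
    eps = rng.normal(0.0, cfg.noise_sd, size=nu.shape) if cfg.noise_sd > 0 else 0.0
    return Spectrum(nu, m * signal + eps, {"true_temperature": float(T), "taxon": cfg.taxon})


def simulate_calibration(
    cfg: GeneratorConfig,
    temperatures=DEFAULT_TEMPERATURES,
    reps: int = 1,
    seed: int = 0,
) -> CalibrationSet:
    """Laboratory calibration set: ``reps`` spectra per charring temperature."""
    temperatures = list(temperatures)
    if not temperatures:
        raise ValidationError("need at least one calibration temperature")
    root = np.random.default_rng(seed)
    spectra, temps = [], []
    for T in temperatures:
        for r in range(reps):
            s = simulate_spectrum(T, cfg, root.spawn(1)[0])
            s.meta.update({"replicate": r, "source": "modern"})
            spectra.append(s)
            temps.append(T)
    matrix = stack(spectra, cfg.grid)
    return CalibrationSet(matrix, np.asarray(temps), taxon=cfg.taxon)


def simulate_archaeological(
    cfg: GeneratorConfig, true_T: float, n: int, seed: int = 0
) -> SpectralMatrix:
    """n replicate spectra at one (hidden) true temperature, for recovery runs."""
    if n < 1:
        raise ValidationError("need at least one archaeological spectrum")
    root = np.random.default_rng(seed)
    spectra = []
    for i in range(n):
        s = simulate_spectrum(true_T, cfg, root.spawn(1)[0])
        s.meta.update({"source": "archaeological", "replicate": i})
        spectra.append(s)
    return stack(spectra, cfg.grid)


def simulate_count_table(taxa_probs: dict, totals: dict, seed: int = 0) -> TaxonCountTable:
    """Seeded multinomial fragment counts per SU.

    ``taxa_probs`` maps SU -> {taxon: probability} (each summing to 1);
    ``totals`` maps SU -> fragment count.
    """
    rng = np.random.default_rng(seed)
    sus = list(totals)
    taxa = sorted({t for probs in taxa_probs.values() for t in probs})
    data = {}
    for su in sus:
        probs = np.array([taxa_probs[su].get(t, 0.0) for t in taxa], dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValidationError(f"probabilities for SU {su!r} sum to {probs.sum():.6f}, not 1")
        data[su] = rng.multinomial(int(totals[su]), probs)
    return TaxonCountTable(pd.DataFrame(data, index=taxa))
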