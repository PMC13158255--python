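"""Synthetic ATR-FTIR spectra for the eight taxon-part classes of the ptarmigan
crop-content study system.

Each class profile is a set of Gaussian bands whose relative expected heights
encode the published phytochemical fingerprints: fructose bands only in
berries, unsaturated-fatty-acid and triglyceride bands confined to seed-bearing
parts, oxalate/tannin bands dominated by *Salix* stems, cutin and ester bands
peaking in catkins, lignin maximal in *Dryas* leaves, and so on. Absolute
heights are conventions (the source material reports orderings, not
intensities); they are chosen so the orderings hold and then rescaled so every
class's noiseless spectrum has the same Euclidean norm — which makes the
orderings survive per-spectrum vector normalization.

A generated replicate is

    sum of Gaussians (sample-jittered heights)
    + one broad random-Gaussian baseline per replicate
    + iid Gaussian noise,

with all replicates of a sample sharing the same jittered heights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .errors import ValidationError
from .io import CLASS_LABELS, SampleMeta, Spectrum, taxon_part_for

#: Matching tolerance (cm-1) for looking a planted peak up by wavenumber.
#: Kept below the closest inter-band spacing (776 vs 780) so a query never
#: resolves to a neighbouring band.
PEAK_LOOKUP_TOL = 3.0


@dataclass(frozen=True)
class PeakSpec:
    """One Gaussian band: center and width in cm-1, mean height in absorbance units."""

    center: float
    sigma: float
    height: float

    def __post_init__(self) -> None:
        if not 400.0 <= self.center <= 4000.0:
            raise ValidationError(f"peak center {self.center} outside 400-4000 cm-1")
        if not self.sigma > 0:
            raise ValidationError("peak sigma must be positive")
        if not (self.height >= 0 and math.isfinite(self.height)):
            raise ValidationError("peak height must be finite and >= 0")


@dataclass(frozen=True)
class ClassProfile:
    """Expected band pattern of one taxon-part class."""

    label: str
    peaks: tuple[PeakSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple(self.peaks))

    def height(self, wavenumber: float) -> float:
        """Planted height of the peak centered within ±3 cm-1 of ``wavenumber``.

        Returns 0 when no planted band sits there (the band is absent in this
        class). With the nearest-center convention the answer is exact rather
        than polluted by tails of neighbouring bands.
        """
        best, dist = 0.0, PEAK_LOOKUP_TOL
        for p in self.peaks:
            d = abs(p.center - wavenumber)
            if d <= dist:
                best, dist = p.height, d
        return best

    def expected_spectrum(self, wavenumbers: np.ndarray) -> np.ndarray:
        """Noise-free expected absorbance on a grid (sum of the Gaussians)."""
        w = np.asarray(wavenumbers, dtype=float)
        out = np.zeros_like(w)
        for p in self.peaks:
            out += p.height * np.exp(-0.5 * ((w - p.center) / p.sigma) ** 2)
        return out


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation parameters emulating the acquisition protocol.

    The default grid covers the mid-IR 4000-400 cm-1 stored descending (FTIR
    convention) at 2 cm-1 spacing; replicates per sample default to 5 (the
    protocol took five to ten). ``sample_jitter_cv`` is the coefficient of
    variation of the multiplicative log-normal height jitter drawn once per
    sample per peak; ``noise_sd`` and ``baseline_amplitude`` are in absorbance
    units at replicate level.
    """

    grid_min: float = 400.0
    grid_max: float = 4000.0
    grid_step: float = 2.0
    n_samples_per_class: int = 30
    n_replicates: int = 5
    sample_jitter_cv: float = 0.10
    noise_sd: float = 0.01
    baseline_amplitude: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("grid_min", "grid_max", "grid_step", "sample_jitter_cv",
                     "noise_sd", "baseline_amplitude"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValidationError(f"{name} must be finite, got {v!r}")
        if not self.grid_min < self.grid_max:
            raise ValidationError("grid_min must be < grid_max")
        if not self.grid_step > 0:
            raise ValidationError("grid_step must be > 0")
        if min(self.sample_jitter_cv, self.noise_sd, self.baseline_amplitude) < 0:
            raise ValidationError("variance parameters must be >= 0")
        if self.n_samples_per_class < 1 or self.n_replicates < 1:
            raise ValidationError("counts must be >= 1")

    def grid(self) -> np.ndarray:
        """Descending wavenumber grid grid_max ... grid_min."""
        n = int(math.floor((self.grid_max - self.grid_min) / self.grid_step)) + 1
        return self.grid_max - self.grid_step * np.arange(n)


# ---------------------------------------------------------------------------
# default class profiles

# Raw (pre-equalization) band heights per class, one row per band:
# (center, sigma, {class: height}); absent classes default to 0.
# Column order: IFR=Bn-infructescence, CBn=Bn-catkin, CBp=Bp-catkin,
# En=En-berry, V=V-berry, Sh=Sh-stem, Sp=Sp-stem, D=D-leaf.
_CLASSES = (
    "Bn-infructescence", "Bn-catkin", "Bp-catkin",
    "En-berry", "V-berry", "Sh-stem", "Sp-stem", "D-leaf",
)

_BAND_HEIGHTS: tuple[tuple[float, float, tuple[float, ...]], ...] = (
    # center sigma   IFR   CBn   CBp   En    V     Sh    Sp    D
    (3293.0, 20.0, (0.44, 0.35, 0.35, 0.55, 0.45, 0.40, 0.40, 0.40)),  # O-H (carbohydrate): En>V, IFR>C
    (3559.0, 15.0, (0.22, 0.22, 0.22, 0.05, 0.05, 0.30, 0.28, 0.32)),  # lignin/silica O-H: berries < all others
    (3013.0, 6.0,  (0.30, 0.00, 0.00, 0.16, 0.22, 0.00, 0.00, 0.00)),  # =C-H unsaturated FA: IFR>V>En, else absent
    (2924.0, 12.0, (0.40, 0.50, 0.50, 0.24, 0.30, 0.24, 0.24, 0.24)),  # CH2 asym: C>IFR>V>rest
    (2851.0, 7.0,  (0.24, 0.30, 0.30, 0.14, 0.18, 0.14, 0.14, 0.14)),  # CH2 sym: C>IFR>V>rest
    (1745.0, 4.0,  (0.35, 0.00, 0.00, 0.18, 0.26, 0.00, 0.00, 0.06)),  # triglyceride C=O: IFR>V>En, minor in D, none in C/S
    (1730.0, 4.0,  (0.32, 0.42, 0.50, 0.18, 0.24, 0.10, 0.10, 0.05)),  # ester/ketone C=O: CBp>CBn>IFR>V>En>S>D
    (1720.0, 3.0,  (0.00, 0.00, 0.00, 0.00, 0.00, 0.30, 0.28, 0.00)),  # hydrolysable tannins: distinct in stems
    (1710.0, 3.0,  (0.05, 0.22, 0.30, 0.03, 0.04, 0.00, 0.00, 0.05)),  # cutin ester: CBp>CBn>rest
    (1650.0, 7.0,  (0.38, 0.30, 0.30, 0.15, 0.22, 0.45, 0.30, 0.30)),  # amide I: Sh>IFR>C,Sp,D; V>En
    (1620.0, 4.0,  (0.06, 0.05, 0.05, 0.03, 0.04, 0.45, 0.42, 0.28)),  # oxalate COO-: stems>leaf>rest
    (1605.0, 4.0,  (0.34, 0.26, 0.26, 0.12, 0.18, 0.48, 0.42, 0.34)),  # phenolics: Sh>Sp>L,IFR>C>V>En
    (1540.0, 6.0,  (0.30, 0.24, 0.24, 0.12, 0.17, 0.35, 0.24, 0.24)),  # amide II: Sh>IFR>C,Sp,D; V>En
    (1516.0, 4.0,  (0.26, 0.26, 0.20, 0.08, 0.13, 0.33, 0.20, 0.40)),  # lignin aromatic: L>Sh>IFR,CBn>CBp,Sp>V>En
    (1315.0, 6.0,  (0.06, 0.05, 0.05, 0.03, 0.04, 0.42, 0.40, 0.26)),  # oxalate + tannins: stems>leaf>rest
    (1025.0, 8.0,  (0.42, 0.30, 0.30, 0.50, 0.40, 0.30, 0.45, 0.38)),  # cellulose C-O: En>V, Sp>D>Sh, IFR>C
    (996.0,  5.0,  (0.12, 0.06, 0.06, 0.30, 0.22, 0.20, 0.20, 0.20)),  # cellulose C-OH: En>V, C<IFR<rest
    (817.0,  3.0,  (0.00, 0.00, 0.00, 0.15, 0.14, 0.00, 0.00, 0.00)),  # fructose C-C-H: berries only
    (780.0,  3.0,  (0.00, 0.00, 0.00, 0.00, 0.00, 0.40, 0.38, 0.22)),  # Ca-oxalate: stems>leaf>rest
    (776.0,  3.0,  (0.00, 0.00, 0.00, 0.15, 0.13, 0.00, 0.00, 0.00)),  # fructose C-C-H: berries only
    (763.0,  3.0,  (0.00, 0.00, 0.00, 0.00, 0.00, 0.20, 0.18, 0.00)),  # gallotannins: distinct in stems
)


def default_class_profiles(
    equalize_norms: bool = True,
) -> dict[str, ClassProfile]:
    """Band-pattern profiles for the eight observed taxon-part classes.

    With ``equalize_norms`` (the default) each class's heights are rescaled so
    its noiseless spectrum on the default grid has unit Euclidean norm. Since
    every measured spectrum is vector-normalized before analysis, equalized
    profiles make the planted cross-class height orderings identical to the
    orderings of the normalized band features.
    """
    assert _CLASSES == CLASS_LABELS  # one profile per observed taxon-part class
    grid = SyntheticConfig().grid()
    profiles: dict[str, ClassProfile] = {}
    for j, label in enumerate(_CLASSES):
        peaks = tuple(
            PeakSpec(center=c, sigma=s, height=heights[j])
            for c, s, heights in _BAND_HEIGHTS
            if heights[j] > 0
        )
        prof = ClassProfile(label=label, peaks=peaks)
        if equalize_norms:
            norm = float(np.linalg.norm(prof.expected_spectrum(grid)))
            prof = ClassProfile(
                label=label,
                peaks=tuple(replace(p, height=p.height / norm) for p in peaks),
            )
        profiles[label] = prof
    return profiles


# ---------------------------------------------------------------------------
# generation


def _jitter_factors(n: int, cv: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative log-normal factors with mean exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(n)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=n)


def generate_spectrum(
    profile: ClassProfile,
    config: SyntheticConfig,
    rng: np.random.Generator | int | None = None,
    sample_id: str = "sample",
) -> list[Spectrum]:
    """Generate one sample's replicate spectra (``config.n_replicates`` of them).

    Heights are jittered once per sample (shared by all replicates); each
    replicate then gets its own broad random baseline and iid Gaussian noise.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    grid = config.grid()
    factors = _jitter_factors(len(profile.peaks), config.sample_jitter_cv, rng)
    base = np.zeros_like(grid)
    for p, f in zip(profile.peaks, factors):
        base += p.height * f * np.exp(-0.5 * ((grid - p.center) / p.sigma) ** 2)
    out = []
    for r in range(config.n_replicates):
        if config.baseline_amplitude > 0:
            amp = rng.uniform(-config.baseline_amplitude, config.baseline_amplitude)
            center = rng.uniform(config.grid_min, config.grid_max)
            width = rng.uniform(300.0, 800.0)
            baseline = amp * np.exp(-0.5 * ((grid - center) / width) ** 2)
        else:
            baseline = 0.0
        noise = rng.normal(0.0, config.noise_sd, size=grid.size) if config.noise_sd > 0 else 0.0
        out.append(
            Spectrum(
                wavenumbers=grid.copy(),
                absorbance=base + baseline + noise,
                sample_id=sample_id,
                replicate_id=f"r{r + 1}",
            )
        )
    return out


def generate_dataset(
    config: SyntheticConfig | None = None,
    profiles: Mapping[str, ClassProfile] | None = None,
) -> tuple[list[Spectrum], list[SampleMeta]]:
    """Generate the full synthetic dataset: 8 classes x n_samples_per_class
    samples x n_replicates replicate spectra, plus per-sample metadata.

    Deterministic given ``config.seed``: class order, sample ids, years and
    bird ids are all reproduced exactly on regeneration.
    """
    config = config or SyntheticConfig()
    profiles = profiles or default_class_profiles()
    rng = np.random.default_rng(config.seed)
    spectra: list[Spectrum] = []
    metas: list[SampleMeta] = []
    bird_counter = 0
    for label in CLASS_LABELS:
        if label not in profiles:
            raise ValidationError(f"no profile for class {label!r}")
        taxon, part = taxon_part_for(label)
        for i in range(config.n_samples_per_class):
            bird_counter += 1
            sample_id = f"{label}_s{i + 1:02d}"
            metas.append(
                SampleMeta(
                    sample_id=sample_id,
                    taxon=taxon,
                    part=part,
                    year=int(rng.integers(2006, 2015)),
                    bird_id=f"bird{bird_counter:03d}",
                )
            )
            spectra.extend(
                generate_spectrum(profiles[label], config, rng=rng, sample_id=sample_id)
            )
    return spectra, metas


# ---------------------------------------------------------------------------
# profile-library serialization


def profiles_to_yaml(profiles: Mapping[str, ClassProfile], path: str | Path) -> None:
    """Write a profile library to YAML (heights are conventions, not measured
    intensities; only their orderings are meaningful)."""
    doc = {
        label: [
            {"center": p.center, "sigma": p.sigma, "height": p.height}
            for p in prof.peaks
        ]
        for label, prof in profiles.items()
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def profiles_from_yaml(path: str | Path) -> dict[str, ClassProfile]:
    doc = yaml.safe_load(Path(path).read_text())
    return {
        label: ClassProfile(
            label=label,
            peaks=tuple(PeakSpec(**p) for p in peaks),
        )
        for label, peaks in doc.items()
    }
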