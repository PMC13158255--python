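"""Band-aggregate peak-height features.

A band aggregate is a named wavenumber window tied to a presumed phytochemical
group; the feature extracted per sample is the *absolute peak height*: the
maximum of the vector-normalized absorbance over the grid points inside the
closed window, without local baseline correction. A baseline-corrected variant
(height above the straight line through the window endpoints) is available
behind a flag for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CoverageError, DataError, ValidationError
from .io import SampleMeta, Spectrum

LabelMode = Literal["part", "taxon_part"]


@dataclass(frozen=True)
class BandAggregate:
    """A named wavenumber window [wn_lo, wn_hi] with its phytochemical group."""

    name: str
    group: str
    wn_lo: float
    wn_hi: float

    def __post_init__(self) -> None:
        if not 400.0 <= self.wn_lo < self.wn_hi <= 4000.0:
            raise ValidationError(
                f"band {self.name!r}: window [{self.wn_lo}, {self.wn_hi}] invalid "
                "(need 400 <= lo < hi <= 4000)"
            )


# Default aggregates, one per assigned band of interest. Point assignments are
# widened to +-4 cm-1 (one resolution element); ranged assignments use their
# printed bounds. Groups: nutritional carbohydrate / lipid / protein,
# structural defense, chemical defense.
_DEFAULT_BANDS: tuple[tuple[str, str, float, float], ...] = (
    ("carbohydrate_oh_3293", "nutritional_carbohydrate", 3289, 3297),
    ("lignin_silica_3560", "structural_defense", 3533, 3585),
    ("unsat_fatty_acid_3013", "nutritional_lipid", 3000, 3020),
    ("ch2_asym_2924", "lipid", 2912, 2936),
    ("ch2_sym_2851", "lipid", 2850, 2852),
    ("triglyceride_1745", "nutritional_lipid", 1741, 1751),
    ("ester_1730", "lipid", 1726, 1734),
    ("tannin_1720", "chemical_defense", 1716, 1724),
    ("cutin_1710", "structural_defense", 1706, 1714),
    ("amide_i_1650", "nutritional_protein", 1646, 1654),
    ("oxalate_1620", "chemical_defense", 1616, 1624),
    ("phenolics_1605", "chemical_defense", 1600, 1610),
    ("amide_ii_1540", "nutritional_protein", 1536, 1544),
    ("lignin_1515", "structural_defense", 1515, 1518),
    ("oxalate_tannin_1315", "chemical_defense", 1311, 1319),
    ("cellulose_1025", "structural_defense", 1010, 1035),
    ("cellulose_996", "structural_defense", 992, 1000),
    ("fructose_818", "nutritional_carbohydrate", 814, 822),
    ("oxalate_780", "chemical_defense", 776, 784),
    ("fructose_776", "nutritional_carbohydrate", 772, 780),
    ("gallotannin_763", "chemical_defense", 759, 767),
)


def default_band_aggregates() -> list[BandAggregate]:
    """The 21 default band aggregates covering the assigned bands of interest."""
    return [BandAggregate(name=n, group=g, wn_lo=lo, wn_hi=hi)
            for n, g, lo, hi in _DEFAULT_BANDS]


def peak_height(
    s: Spectrum, band: BandAggregate, baseline_corrected: bool = False
) -> float:
    """Absolute peak height of a spectrum within a band window.

    The signed maximum of the absorbance over grid points with
    ``wn_lo <= w <= wn_hi``. With ``baseline_corrected=True`` the straight line
    through the window's endpoint absorbances is subtracted first.
    """
    mask = (s.wavenumbers >= band.wn_lo) & (s.wavenumbers <= band.wn_hi)
    if not mask.any():
        raise CoverageError(
            f"band {band.name!r} [{band.wn_lo}, {band.wn_hi}] covers no grid "
            f"point of spectrum {s.key()}"
        )
    a = s.absorbance[mask]
    if baseline_corrected and a.size > 2:
        w = s.wavenumbers[mask]
        slope = (a[-1] - a[0]) / (w[-1] - w[0]) if w[-1] != w[0] else 0.0
        a = a - (a[0] + slope * (w - w[0]))
    return float(a.max())


@dataclass
class FeatureTable:
    """Samples x band-aggregates matrix of peak heights with class labels."""

    sample_ids: list[str]
    class_labels: list[str]
    matrix: np.ndarray
    aggregate_names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n, p = self.matrix.shape
        if len(self.sample_ids) != n or len(self.class_labels) != n:
            raise ValidationError("sample_ids/class_labels length mismatch with matrix")
        if len(self.aggregate_names) != p:
            raise ValidationError("aggregate_names length mismatch with matrix")
        if not np.all(np.isfinite(self.matrix)):
            raise DataError("feature matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.aggregate_names)
        df.insert(0, "sample_id", self.sample_ids)
        df["class"] = self.class_labels
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format='%.17g')

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path, dtype={"sample_id": str, "class": str}, float_precision="round_trip")
        for col in ("sample_id", "class"):
            if col not in df.columns:
                raise DataError(f"{path}: missing column {col!r}")
        names = [c for c in df.columns if c not in ("sample_id", "class")]
        return cls(
            sample_ids=df["sample_id"].tolist(),
            class_labels=df["class"].tolist(),
            matrix=df[names].to_numpy(float),
            aggregate_names=names,
        )


def build_feature_table(
    samples: Sequence[Spectrum],
    meta: Sequence[SampleMeta] | Mapping[str, SampleMeta],
    bands: Sequence[BandAggregate] | None = None,
    label_mode: LabelMode = "part",
    baseline_corrected: bool = False,
) -> FeatureTable:
    """Extract the samples x bands peak-height matrix with class labels.

    ``samples`` are preprocessed (normalized, replicate-averaged, excised)
    sample spectra; row order follows input order. ``label_mode='part'`` labels
    rows by the five plant parts (collapsing e.g. the two catkin taxa);
    ``'taxon_part'`` keeps the eight taxon-part classes.
    """
    bands = list(bands) if bands is not None else default_band_aggregates()
    if label_mode not in ("part", "taxon_part"):
        raise ValidationError(f"unknown label_mode {label_mode!r}")
    meta_by_id = (
        dict(meta) if isinstance(meta, Mapping) else {m.sample_id: m for m in meta}
    )
    orphans = [s.sample_id for s in samples if s.sample_id not in meta_by_id]
    if orphans:
        raise DataError(f"samples without metadata: {sorted(set(orphans))}")
    rows = np.array(
        [[peak_height(s, b, baseline_corrected) for b in bands] for s in samples]
    ).reshape(len(samples), len(bands))
    labels = [
        meta_by_id[s.sample_id].part
        if label_mode == "part"
        else meta_by_id[s.sample_id].class_label
        for s in samples
    ]
    return FeatureTable(
        sample_ids=[s.sample_id for s in samples],
        class_labels=labels,
        matrix=rows,
        aggregate_names=[b.name for b in bands],
    )
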