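"""Reading and writing spectra, sample metadata, band tables and evaluation reports.

Two CSV dialects are supported for spectra:

* ``long`` — one row per measured point with columns
  ``sample_id, replicate_id, wavenumber_cm1, absorbance``;
* ``wide`` — one row per replicate, with ``sample_id, replicate_id`` followed by
  one column per wavenumber.

Both dialects round-trip at full floating precision and preserve input order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, ValidationError

logger = logging.getLogger(__name__)

# The seven plant taxa and five plant parts recovered from ptarmigan crop
# contents, and the eight taxon-part combinations actually observed.
TAXA = (
    "B. nana",
    "B. pubescens",
    "E. nigrum",
    "Vaccinium spp.",
    "S. herbacea",
    "S. phylicifolia",
    "D. octopetala",
)
PARTS = ("infructescence", "catkin", "berry", "stem-with-buds", "leaf")

TAXON_PART_CLASSES: dict[tuple[str, str], str] = {
    ("B. nana", "infructescence"): "Bn-infructescence",
    ("B. nana", "catkin"): "Bn-catkin",
    ("B. pubescens", "catkin"): "Bp-catkin",
    ("E. nigrum", "berry"): "En-berry",
    ("Vaccinium spp.", "berry"): "V-berry",
    ("S. herbacea", "stem-with-buds"): "Sh-stem",
    ("S. phylicifolia", "stem-with-buds"): "Sp-stem",
    ("D. octopetala", "leaf"): "D-leaf",
}
CLASS_LABELS = tuple(TAXON_PART_CLASSES.values())
_CLASS_TO_TAXON_PART = {v: k for k, v in TAXON_PART_CLASSES.items()}


def class_label(taxon: str, part: str) -> str:
    """Return the canonical taxon-part class label for an observed combination."""
    try:
        return TAXON_PART_CLASSES[(taxon, part)]
    except KeyError:
        raise ValidationError(
            f"({taxon!r}, {part!r}) is not one of the {len(TAXON_PART_CLASSES)} "
            "taxon-part combinations observed in crop contents"
        ) from None


def taxon_part_for(label: str) -> tuple[str, str]:
    """Inverse of :func:`class_label`."""
    try:
        return _CLASS_TO_TAXON_PART[label]
    except KeyError:
        raise ValidationError(f"unknown class label {label!r}") from None


@dataclass
class Spectrum:
    """A single absorbance spectrum on a strictly monotone wavenumber grid.

    ``replicate_id is None`` marks a replicate-averaged sample spectrum.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    sample_id: str
    replicate_id: str | None = None

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavenumbers.ndim != 1 or self.absorbance.ndim != 1:
            raise ValidationError("wavenumbers and absorbance must be 1-D")
        if self.wavenumbers.shape != self.absorbance.shape:
            raise ValidationError(
                f"grid/absorbance length mismatch for {self.key()}: "
                f"{self.wavenumbers.size} vs {self.absorbance.size}"
            )
        diffs = np.diff(self.wavenumbers)
        if diffs.size and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValidationError(
                f"wavenumber grid of {self.key()} is not strictly monotone"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise DataError(f"non-finite absorbance in {self.key()}")

    def key(self) -> str:
        rep = "<avg>" if self.replicate_id is None else self.replicate_id
        return f"{self.sample_id}/{rep}"

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    def with_values(
        self,
        wavenumbers: np.ndarray | None = None,
        absorbance: np.ndarray | None = None,
        replicate_id: str | None | type(...) = ...,
    ) -> "Spectrum":
        """Copy, replacing selected fields."""
        return Spectrum(
            wavenumbers=self.wavenumbers if wavenumbers is None else wavenumbers,
            absorbance=self.absorbance if absorbance is None else absorbance,
            sample_id=self.sample_id,
            replicate_id=self.replicate_id if replicate_id is ... else replicate_id,
        )


@dataclass(frozen=True)
class SampleMeta:
    """Identity and labels of one pure plant fraction (one sample)."""

    sample_id: str
    taxon: str
    part: str
    year: int | None = None
    bird_id: str | None = None
    class_label: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "class_label", class_label(self.taxon, self.part))


# ---------------------------------------------------------------------------
# spectra

LONG_COLUMNS = ["sample_id", "replicate_id", "wavenumber_cm1", "absorbance"]


def _normalise_replicate(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value)
    return None if s == "" else s


def read_spectra(path: str | Path, dialect: str = "long") -> list[Spectrum]:
    """Read spectra from CSV in the ``long`` or ``wide`` dialect.

    Rows with non-numeric absorbance are dropped (count logged). Input order of
    (sample, replicate) groups is preserved.
    """
    path = Path(path)
    if dialect == "long":
        df = pd.read_csv(path, dtype={"sample_id": str, "replicate_id": str}, float_precision="round_trip")
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
        absorb = pd.to_numeric(df["absorbance"], errors="coerce")
        bad = absorb.isna() & df["absorbance"].notna() | df["absorbance"].isna()
        n_bad = int(bad.sum())
        if n_bad:
            logger.warning("%s: dropped %d rows with non-numeric absorbance", path, n_bad)
            df = df[~bad]
            absorb = absorb[~bad]
        df = df.assign(absorbance=absorb)
        spectra: list[Spectrum] = []
        lengths: dict[str, int] = {}
        for (sid, rid), grp in df.groupby(
            ["sample_id", "replicate_id"], sort=False, dropna=False
        ):
            rid = _normalise_replicate(rid)
            try:
                s = Spectrum(
                    wavenumbers=grp["wavenumber_cm1"].to_numpy(float),
                    absorbance=grp["absorbance"].to_numpy(float),
                    sample_id=str(sid),
                    replicate_id=rid,
                )
            except ValidationError as exc:
                raise DataError(f"{path}: {exc}") from exc
            if sid in lengths and lengths[sid] != len(s):
                raise DataError(
                    f"{path}: replicate {s.key()} has grid length {len(s)}, "
                    f"other replicates of {sid!r} have {lengths[sid]}"
                )
            lengths.setdefault(str(sid), len(s))
            spectra.append(s)
        return spectra
    if dialect == "wide":
        df = pd.read_csv(path, dtype={"sample_id": str, "replicate_id": str}, float_precision="round_trip")
        for col in ("sample_id", "replicate_id"):
            if col not in df.columns:
                raise FormatError(f"{path}: missing column {col!r}")
        wn_cols = [c for c in df.columns if c not in ("sample_id", "replicate_id")]
        try:
            grid = np.array([float(c) for c in wn_cols])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric wavenumber column: {exc}") from exc
        spectra = []
        for _, row in df.iterrows():
            try:
                spectra.append(
                    Spectrum(
                        wavenumbers=grid.copy(),
                        absorbance=row[wn_cols].to_numpy(float),
                        sample_id=str(row["sample_id"]),
                        replicate_id=_normalise_replicate(row["replicate_id"]),
                    )
                )
            except (ValidationError, ValueError) as exc:
                raise DataError(f"{path}: {exc}") from exc
        return spectra
    raise ValidationError(f"unknown spectra dialect {dialect!r}")


def write_spectra(spectra: Sequence[Spectrum], path: str | Path, dialect: str = "long") -> None:
    """Write spectra to CSV; inverse of :func:`read_spectra`."""
    path = Path(path)
    if dialect == "long":
        frames = [
            pd.DataFrame(
                {
                    "sample_id": s.sample_id,
                    "replicate_id": "" if s.replicate_id is None else s.replicate_id,
                    "wavenumber_cm1": s.wavenumbers,
                    "absorbance": s.absorbance,
                }
            )
            for s in spectra
        ]
        pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format='%.17g')
        return
    if dialect == "wide":
        if not spectra:
            raise ValidationError("cannot write an empty wide table")
        grid = spectra[0].wavenumbers
        for s in spectra:
            if not np.array_equal(s.wavenumbers, grid):
                raise DataError(f"wide dialect needs a common grid; {s.key()} differs")
        df = pd.DataFrame(
            [s.absorbance for s in spectra],
            columns=[repr(float(w)) for w in grid],
        )
        df.insert(0, "replicate_id", ["" if s.replicate_id is None else s.replicate_id for s in spectra])
        df.insert(0, "sample_id", [s.sample_id for s in spectra])
        df.to_csv(path, index=False, float_format='%.17g')
        return
    raise ValidationError(f"unknown spectra dialect {dialect!r}")


# ---------------------------------------------------------------------------
# metadata

META_COLUMNS = ["sample_id", "taxon", "part", "class", "year", "bird_id"]


def read_metadata(path: str | Path) -> list[SampleMeta]:
    """Read the sample metadata CSV (sample_id, taxon, part[, class, year, bird_id])."""
    df = pd.read_csv(path, dtype={"sample_id": str, "bird_id": str})
    missing = [c for c in ("sample_id", "taxon", "part") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    metas = []
    for _, row in df.iterrows():
        year = row.get("year")
        year = None if pd.isna(year) else int(year)
        bird = row.get("bird_id")
        bird = None if pd.isna(bird) else str(bird)
        metas.append(
            SampleMeta(
                sample_id=str(row["sample_id"]),
                taxon=str(row["taxon"]),
                part=str(row["part"]),
                year=year,
                bird_id=bird,
            )
        )
    return metas


def write_metadata(metas: Iterable[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in metas],
            "taxon": [m.taxon for m in metas],
            "part": [m.part for m in metas],
            "class": [m.class_label for m in metas],
            "year": [m.year for m in metas],
            "bird_id": [m.bird_id for m in metas],
        }
    ).to_csv(path, index=False, float_format='%.17g')


# ---------------------------------------------------------------------------
# band tables


def read_band_table(path: str | Path) -> list:
    """Read a band-aggregate table (columns ``name, group, wn_lo, wn_hi``).

    Overlapping windows are permitted (adjacent bands genuinely overlap in the
    fingerprint region) but are logged so they can be audited.
    """
    from .features import BandAggregate  # local import to avoid a cycle

    df = pd.read_csv(path)
    missing = [c for c in ("name", "group", "wn_lo", "wn_hi") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    bands = [
        BandAggregate(
            name=str(r["name"]),
            group=str(r["group"]),
            wn_lo=float(r["wn_lo"]),
            wn_hi=float(r["wn_hi"]),
        )
        for _, r in df.iterrows()
    ]
    for i, a in enumerate(bands):
        for b in bands[i + 1 :]:
            if a.wn_lo <= b.wn_hi and b.wn_lo <= a.wn_hi:
                logger.info("band windows overlap: %s and %s", a.name, b.name)
    return bands


def write_band_table(bands: Sequence, path: str | Path) -> None:
    pd.DataFrame(
        {
            "name": [b.name for b in bands],
            "group": [b.group for b in bands],
            "wn_lo": [b.wn_lo for b in bands],
            "wn_hi": [b.wn_hi for b in bands],
        }
    ).to_csv(path, index=False, float_format='%.17g')


# ---------------------------------------------------------------------------
# evaluation reports


def write_report(report, path: str | Path, format: str = "json") -> None:
    """Serialize an :class:`~spectradiet.classify.EvalReport`.

    JSON holds the full nested report (classes sorted lexicographically by
    construction); CSV is a flat tidy table of named values, with the confusion
    matrix in ``confusion[true][pred]`` long form.
    """
    path = Path(path)
    d = report.to_dict()
    if format == "json":
        path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
        return
    if format == "csv":
        rows: list[tuple[str, object]] = []
        for k in ("overall_accuracy", "ci95_lo", "ci95_hi", "kappa", "oob_error_pct"):
            rows.append((k, d[k]))
        for cls, stats in d["per_class"].items():
            for stat, val in stats.items():
                rows.append((f"per_class[{cls}][{stat}]", val))
        labels = d["labels"]
        for i, t in enumerate(labels):
            for j, p in enumerate(labels):
                rows.append((f"confusion[{t}][{p}]", d["confusion"][i][j]))
        for name, imp in d["importances"].items():
            rows.append((f"importance[{name}]", imp))
        for k, v in d["chosen_hyperparameters"].items():
            rows.append((f"hyperparameter[{k}]", v))
        pd.DataFrame(rows, columns=["metric", "value"]).to_csv(path, index=False, float_format='%.17g')
        return
    raise ValidationError(f"unknown report format {format!r}")


def read_report(path: str | Path):
    """Read a JSON report back into an :class:`~spectradiet.classify.EvalReport`."""
    from .classify import EvalReport

    return EvalReport.from_dict(json.loads(Path(path).read_text()))
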