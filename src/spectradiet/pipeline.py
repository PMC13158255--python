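"""End-to-end orchestration: input -> preprocess -> features -> PCA -> RF models.

Every stage reads and writes plain files under the run's output directory, so a
run can be audited afterwards; a JSON manifest records versions, the seed, the
paths of all products and the summary metrics. Identical seed and config give
metric-identical manifests.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import RFConfig, run_classification
from .errors import PipelineStageError, ValidationError
from .features import FeatureTable, build_feature_table, default_band_aggregates
from .io import (
    Spectrum,
    read_band_table,
    read_metadata,
    read_spectra,
    write_metadata,
    write_report,
    write_spectra,
)
from .ordination import loading_extrema, run_pca
from .preprocess import PreprocessConfig, preprocess_sample
from .synthetic import SyntheticConfig, generate_dataset

logger = logging.getLogger(__name__)


def _pkg_version() -> str:
    from . import __version__

    return __version__


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    input_mode: str = "synthetic"  # "synthetic" | "files"
    output_dir: str = "spectradiet_run"
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    rf: RFConfig = field(default_factory=RFConfig)
    band_table: str = "default"  # "default" or a CSV path
    spectra_path: str | None = None
    spectra_dialect: str = "long"
    metadata_path: str | None = None

    def __post_init__(self) -> None:
        if self.input_mode not in ("synthetic", "files"):
            raise ValidationError(f"unknown input_mode {self.input_mode!r}")
        if self.input_mode == "files" and not (self.spectra_path and self.metadata_path):
            raise ValidationError("files mode needs spectra_path and metadata_path")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {
            k: doc[k]
            for k in (
                "input_mode", "output_dir", "seed", "band_table",
                "spectra_path", "spectra_dialect", "metadata_path",
            )
            if k in doc
        }
        if "synthetic" in doc:
            kwargs["synthetic"] = SyntheticConfig(**doc["synthetic"])
        if "preprocess" in doc:
            kwargs["preprocess"] = PreprocessConfig(**doc["preprocess"])
        if "rf" in doc:
            rf = dict(doc["rf"])
            for g in ("mtry_grid", "ntree_grid", "maxnodes_grid", "nodesize_grid"):
                if g in rf:
                    rf[g] = tuple(rf[g])
            kwargs["rf"] = RFConfig(**rf)
        cfg = cls(**kwargs)
        # one user-visible seed drives every source of randomness
        if "seed" in doc:
            cfg = replace(
                cfg,
                synthetic=replace(cfg.synthetic, seed=doc["seed"]),
                rf=replace(cfg.rf, seed=doc["seed"]),
            )
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "input_mode": self.input_mode,
            "output_dir": self.output_dir,
            "seed": self.seed,
            "band_table": self.band_table,
            "spectra_path": self.spectra_path,
            "spectra_dialect": self.spectra_dialect,
            "metadata_path": self.metadata_path,
            "synthetic": asdict(self.synthetic),
            "preprocess": asdict(self.preprocess),
            "rf": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self.rf).items()
            },
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def _group_replicates(spectra: list[Spectrum]) -> dict[str, list[Spectrum]]:
    groups: dict[str, list[Spectrum]] = {}
    for s in spectra:
        groups.setdefault(s.sample_id, []).append(s)
    return groups


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run manifest.

    Products written under ``config.output_dir``: averaged spectra, feature
    tables (part and taxon-part labelings), PCA scores/loadings and loading
    extrema, RFp and RFtp evaluation reports, and ``manifest.json``.
    """
    t0 = time.perf_counter()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _stage(name, fn):
        try:
            return fn()
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError(name, exc) from exc

    def _input():
        if config.input_mode == "synthetic":
            syn = replace(config.synthetic, seed=config.seed)
            spectra, metas = generate_dataset(syn)
        else:
            spectra = read_spectra(config.spectra_path, config.spectra_dialect)
            metas = read_metadata(config.metadata_path)
        logger.info("input: %d replicate spectra, %d samples", len(spectra), len(metas))
        return spectra, metas

    spectra, metas = _stage("input", _input)

    def _preprocess():
        groups = _group_replicates(spectra)
        averaged = [preprocess_sample(reps, config.preprocess) for reps in groups.values()]
        p = out / "averaged_spectra.csv"
        write_spectra(averaged, p, dialect="long")
        paths["averaged_spectra"] = str(p)
        m = out / "metadata.csv"
        write_metadata(metas, m)
        paths["metadata"] = str(m)
        logger.info("preprocess: %d averaged spectra of length %d", len(averaged), len(averaged[0]))
        return averaged

    averaged = _stage("preprocess", _preprocess)

    def _features():
        bands = (
            default_band_aggregates()
            if config.band_table == "default"
            else read_band_table(config.band_table)
        )
        tables = {}
        for mode in ("part", "taxon_part"):
            ft = build_feature_table(averaged, metas, bands, label_mode=mode)
            p = out / f"features_{mode}.csv"
            ft.to_csv(p)
            paths[f"features_{mode}"] = str(p)
            tables[mode] = ft
        logger.info("features: %d samples x %d bands", tables["part"].n_samples, len(bands))
        return tables

    tables = _stage("features", _features)

    def _pca():
        n_comp = min(10, len(averaged) - 1, len(averaged[0]))
        res = run_pca(averaged, n_components=n_comp)
        labels = {m.sample_id: m.class_label for m in metas}
        sp = out / "pca_scores.csv"
        res.scores_frame([labels[sid] for sid in res.sample_ids]).to_csv(sp, index=False)
        lp = out / "pca_loadings.csv"
        res.loadings_frame().to_csv(lp, index=False)
        rows = []
        for comp in (1, 2):
            for wn, loading in loading_extrema(res, comp, k=10):
                rows.append({"component": comp, "wavenumber_cm1": wn, "loading": loading})
        ep = out / "loading_extrema.csv"
        pd.DataFrame(rows).to_csv(ep, index=False)
        paths.update(pca_scores=str(sp), pca_loadings=str(lp), loading_extrema=str(ep))
        logger.info("pca: explained %% = %s", np.round(res.explained_pct[:3], 2))
        return res

    pca = _stage("pca", _pca)

    reports = {}
    for short, mode in (("rfp", "part"), ("rftp", "taxon_part")):
        def _rf(mode=mode, short=short):
            rf_cfg = replace(config.rf, seed=config.seed)
            report, result, _ = run_classification(tables[mode], rf_cfg)
            p = out / f"{short}_report.json"
            write_report(report, p, format="json")
            paths[f"{short}_report"] = str(p)
            cvp = out / f"{short}_cv_table.csv"
            result.cv_table.to_csv(cvp, index=False)
            paths[f"{short}_cv_table"] = str(cvp)
            logger.info(
                "%s: accuracy=%.3f kappa=%.3f oob_error=%.2f%%",
                short, report.overall_accuracy, report.kappa, report.oob_error_pct,
            )
            return report

        reports[short] = _stage(short, _rf)

    manifest = {
        "versions": {
            "spectradiet": _pkg_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": __import__("sklearn").__version__,
        },
        "seed": config.seed,
        "input_mode": config.input_mode,
        "n_samples": len(metas),
        "n_replicate_spectra": len(spectra),
        "outputs": paths,
        "metrics": {
            "pc1_explained_pct": float(pca.explained_pct[0]),
            "pc2_explained_pct": float(pca.explained_pct[1]) if pca.n_components > 1 else None,
            "rfp_accuracy": reports["rfp"].overall_accuracy,
            "rfp_kappa": reports["rfp"].kappa,
            "rfp_oob_error_pct": reports["rfp"].oob_error_pct,
            "rftp_accuracy": reports["rftp"].overall_accuracy,
            "rftp_kappa": reports["rftp"].kappa,
            "rftp_oob_error_pct": reports["rftp"].oob_error_pct,
        },
        "wall_time_s": round(time.perf_counter() - t0, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def make_fixtures(out_dir: str | Path, seed: int = 0) -> dict[str, str]:
    """Write a small canonical synthetic dataset (8 classes x 5 samples x 5
    replicates) plus its expected taxon-part feature table; byte-identical
    under the same seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = SyntheticConfig(n_samples_per_class=5, n_replicates=5, seed=seed)
    spectra, metas = generate_dataset(cfg)
    sp = out / "spectra.csv"
    write_spectra(spectra, sp, dialect="long")
    mp = out / "metadata.csv"
    write_metadata(metas, mp)
    averaged = [
        preprocess_sample(reps, PreprocessConfig())
        for reps in _group_replicates(spectra).values()
    ]
    ft = build_feature_table(averaged, metas, label_mode="taxon_part")
    fp = out / "expected_features.csv"
    ft.to_csv(fp)
    return {"spectra": str(sp), "metadata": str(mp), "expected_features": str(fp)}
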