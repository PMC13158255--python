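"""Covariance-mode PCA of preprocessed spectra.

Input spectra are vector-normalized, replicate-averaged and excised; the PCA
itself column-mean-centers but does not scale to unit variance (the default of
the usual spectroscopic workflow, where all variables share units). Computed by
singular value decomposition with a deterministic sign convention: each
loading vector is flipped so its largest-magnitude element is positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError, DegenerateInputError, ValidationError
from .io import Spectrum


@dataclass
class PCAResult:
    """Scores, loadings and percent variance explained.

    ``scores`` is samples x components, ``loadings`` components x wavenumbers
    (rows orthonormal), ``explained_pct`` the percentage of total (centered)
    variance per component, ``center_vector`` the per-wavenumber mean that was
    subtracted.
    """

    scores: np.ndarray
    loadings: np.ndarray
    explained_pct: np.ndarray
    center_vector: np.ndarray
    wavenumbers: np.ndarray
    sample_ids: list[str]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def reconstruct(self) -> np.ndarray:
        """Centered data approximation scores @ loadings (exact with all
        components)."""
        return self.scores @ self.loadings

    def scores_frame(self, labels: Sequence[str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            self.scores,
            columns=[f"PC{i + 1}" for i in range(self.n_components)],
        )
        df.insert(0, "sample_id", self.sample_ids)
        if labels is not None:
            df["label"] = list(labels)
        return df

    def loadings_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.loadings.T,
            columns=[f"PC{i + 1}" for i in range(self.n_components)],
        )
        df.insert(0, "wavenumber_cm1", self.wavenumbers)
        return df


def run_pca(samples: Sequence[Spectrum], n_components: int | None = None) -> PCAResult:
    """Centered, unscaled PCA of sample spectra sharing a common grid.

    ``explained_pct`` is always relative to the total variance, so it sums to
    at most 100 regardless of how many components are retained.
    """
    if len(samples) < 2:
        raise DegenerateInputError("PCA needs at least 2 samples")
    grid = samples[0].wavenumbers
    for s in samples[1:]:
        if not np.array_equal(s.wavenumbers, grid):
            raise DataError(f"sample {s.key()} is not on the common grid")
    X = np.vstack([s.absorbance for s in samples])
    center = X.mean(axis=0)
    Xc = X - center
    max_rank = min(X.shape[0] - 1, X.shape[1])
    if n_components is None:
        n_components = max_rank
    if not 1 <= n_components <= max_rank:
        raise ValidationError(
            f"n_components must be in [1, {max_rank}], got {n_components}"
        )
    U, sv, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = float((sv**2).sum())
    if total_var == 0.0:
        raise DegenerateInputError("all samples identical; PCA undefined")
    # deterministic sign: largest-|.| element of each loading made positive
    for i in range(n_components):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    scores = U[:, :n_components] * sv[:n_components]
    return PCAResult(
        scores=scores,
        loadings=Vt[:n_components],
        explained_pct=100.0 * sv[:n_components] ** 2 / total_var,
        center_vector=center,
        wavenumbers=grid.copy(),
        sample_ids=[s.sample_id for s in samples],
    )


def loading_extrema(
    result: PCAResult, component: int, k: int
) -> list[tuple[float, float]]:
    """The k most positive and k most negative loadings of one component.

    ``component`` is 1-based (PC1, PC2, ...). Returns (wavenumber, loading)
    pairs, most positive first, then most negative last; with k=0 an empty
    list.
    """
    if not 1 <= component <= result.n_components:
        raise ValidationError(
            f"component {component} out of range 1..{result.n_components}"
        )
    if k < 0:
        raise ValidationError("k must be >= 0")
    if k == 0:
        return []
    v = result.loadings[component - 1]
    order = np.argsort(v)  # ascending
    neg = order[: min(k, v.size)]
    pos = order[-min(k, v.size):][::-1]
    out = [(float(result.wavenumbers[i]), float(v[i])) for i in pos]
    out += [(float(result.wavenumbers[i]), float(v[i])) for i in reversed(neg)]
    return out
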