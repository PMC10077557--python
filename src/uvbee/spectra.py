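"""UV-Vis spectrum containers, wide-CSV I/O, scan averaging and PCA features.

Spectra live on a fixed wavelength grid (default 190-400 nm at 1 nm spacing,
211 points). The on-disk format is a wide CSV: first column the wavelength in
nm, one column per sample, the header of each sample column carrying
``label;concentration`` metadata.

PCA is computed on mean-centered, unscaled absorbances via singular value
decomposition. Loading-vector signs are fixed by making the largest-magnitude
element of each component positive, so fitted models are deterministic up to
sample order. Test spectra are projected with a stored model — never refit.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "DEFAULT_GRID",
    "default_grid",
    "UVSpectrum",
    "SpectraSet",
    "PCAModel",
    "read_spectra_csv",
    "write_spectra_csv",
    "average_scans",
    "l2_normalize",
    "fit_pca",
    "project",
    "save_pca",
    "load_pca",
]


def default_grid() -> np.ndarray:
    """The 211-point 190..400 nm grid at 1 nm spacing."""
    return np.arange(190.0, 401.0, 1.0)


DEFAULT_GRID = default_grid()


@dataclass
class UVSpectrum:
    """Absorbance versus wavelength with class-label and concentration metadata."""

    wavelengths: np.ndarray
    absorbance: np.ndarray
    label: str = ""
    concentration: float | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths.ndim != 1 or self.wavelengths.shape != self.absorbance.shape:
            raise ValueError("wavelengths and absorbance must be equal-length vectors")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance must be finite")


@dataclass
class SpectraSet:
    """A list of spectra sharing one wavelength grid."""

    spectra: list[UVSpectrum]

    def __post_init__(self) -> None:
        if not self.spectra:
            raise ValueError("SpectraSet needs at least one spectrum")
        grid = self.spectra[0].wavelengths
        for s in self.spectra[1:]:
            if not np.array_equal(s.wavelengths, grid):
                raise ValueError("all spectra must share one wavelength grid")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    @property
    def wavelengths(self) -> np.ndarray:
        return self.spectra[0].wavelengths

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.spectra]

    @property
    def matrix(self) -> np.ndarray:
        """n_samples x n_wavelengths absorbance matrix."""
        return np.vstack([s.absorbance for s in self.spectra])


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def write_spectra_csv(sset: SpectraSet, path: str | Path) -> None:
    """Write the wide CSV; full float precision so read(write(x)) == x."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        header = ["wavelength_nm"]
        for s in sset:
            conc = "" if s.concentration is None else repr(float(s.concentration))
            header.append(f"{s.label};{conc}")
        writer.writerow(header)
        mat = sset.matrix
        for row_i, wl in enumerate(sset.wavelengths):
            writer.writerow([repr(float(wl))] +
                            [repr(float(v)) for v in mat[:, row_i]])


def read_spectra_csv(path: str | Path) -> SpectraSet:
    """Read the wide CSV written by :func:`write_spectra_csv`.

    Errors name the offending line for non-numeric cells, ragged rows and a
    non-monotone wavelength column.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        if len(header) < 2:
            raise ValueError(f"{path}: need a wavelength column plus >= 1 sample column")
        n_cols = len(header)
        wavelengths: list[float] = []
        columns: list[list[float]] = [[] for _ in header[1:]]
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != n_cols:
                raise ValueError(
                    f"{path}: line {line_no}: expected {n_cols} columns, got {len(row)}")
            try:
                values = [float(v) for v in row]
            except ValueError:
                raise ValueError(f"{path}: line {line_no}: non-numeric value") from None
            if wavelengths and values[0] <= wavelengths[-1]:
                raise ValueError(
                    f"{path}: line {line_no}: wavelength column not strictly increasing")
            wavelengths.append(values[0])
            for col, v in zip(columns, values[1:]):
                col.append(v)
    grid = np.asarray(wavelengths)
    spectra = []
    for name, col in zip(header[1:], columns):
        label, _, conc = name.partition(";")
        concentration = float(conc) if conc else None
        spectra.append(UVSpectrum(grid.copy(), np.asarray(col), label, concentration))
    return SpectraSet(spectra)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def average_scans(replicates: list[UVSpectrum]) -> UVSpectrum:
    """Pointwise mean of repeated scans of one sample; metadata from the first."""
    if not replicates:
        raise ValueError("need at least one replicate scan")
    grid = replicates[0].wavelengths
    for rep in replicates[1:]:
        if not np.array_equal(rep.wavelengths, grid):
            raise ValueError("replicate scans must share one wavelength grid")
    mean = np.mean([rep.absorbance for rep in replicates], axis=0)
    first = replicates[0]
    return UVSpectrum(grid.copy(), mean, first.label, first.concentration)


def l2_normalize(sset: SpectraSet) -> SpectraSet:
    """Scale each spectrum to unit Euclidean norm (shape-only classification).

    Concentration varies over orders of magnitude between samples of a class;
    normalizing removes the intensity axis so PCA captures band shape.
    All-zero spectra are left unchanged.
    """
    out = []
    for s in sset:
        norm = float(np.linalg.norm(s.absorbance))
        absorb = s.absorbance / norm if norm > 0 else s.absorbance.copy()
        out.append(UVSpectrum(s.wavelengths.copy(), absorb, s.label, s.concentration))
    return SpectraSet(out)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """Mean spectrum, loading vectors, training scores and variance contributions.

    ``loadings`` is p x k with orthonormal columns; ``scores`` is n x k with
    ``scores = (X - mean) @ loadings``; ``variance_contribution`` holds the
    percentage of total variance carried by each retained component.
    """

    wavelengths: np.ndarray
    mean_spectrum: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    variance_contribution: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def fit_pca(sset: SpectraSet | np.ndarray, k: int,
            wavelengths: np.ndarray | None = None) -> PCAModel:
    """Principal component analysis of mean-centered absorbances.

    Requires ``n >= 2`` samples and ``k <= min(n - 1, p)``. Variance
    contributions use all eigenvalues in the denominator, so they sum to at
    most 100 over the retained components.
    """
    if isinstance(sset, SpectraSet):
        x = sset.matrix
        wavelengths = sset.wavelengths
    else:
        x = np.asarray(sset, dtype=float)
        if wavelengths is None:
            wavelengths = np.arange(x.shape[1], dtype=float)
    n, p = x.shape
    if n < 2:
        raise ValueError("PCA needs at least two samples")
    if not 1 <= k <= min(n - 1, p):
        raise ValueError(f"k must be in 1..{min(n - 1, p)}, got {k}")

    mean = x.mean(axis=0)
    centered = x - mean
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = svals ** 2 / (n - 1)
    total = float(eigenvalues.sum())

    loadings = vt[:k].T.copy()
    # deterministic sign: largest-magnitude loading element positive per PC
    for col in range(k):
        extreme = np.argmax(np.abs(loadings[:, col]))
        if loadings[extreme, col] < 0:
            loadings[:, col] = -loadings[:, col]
    scores = centered @ loadings
    if total > 0:
        contribution = 100.0 * eigenvalues[:k] / total
    else:  # identical samples: no variance at all
        contribution = np.zeros(k)
    return PCAModel(np.asarray(wavelengths, dtype=float), mean, loadings,
                    scores, contribution)


def project(model: PCAModel, spectrum: UVSpectrum) -> np.ndarray:
    """Score vector of a new spectrum under a fitted model."""
    if not np.array_equal(spectrum.wavelengths, model.wavelengths):
        raise ValueError("spectrum grid does not match the PCA model grid")
    return (spectrum.absorbance - model.mean_spectrum) @ model.loadings


def project_set(model: PCAModel, sset: SpectraSet) -> np.ndarray:
    """Score matrix (n x k) of a whole set under a fitted model."""
    return np.vstack([project(model, s) for s in sset])


# ---------------------------------------------------------------------------
# model serialization: CSV pair (loadings, mean) + JSON metadata
# ---------------------------------------------------------------------------

def save_pca(model: PCAModel, prefix: str | Path) -> None:
    """Write ``<prefix>_loadings.csv``, ``<prefix>_mean.csv``, ``<prefix>_meta.json``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(f"{prefix}_loadings.csv", model.loadings, delimiter=",")
    np.savetxt(f"{prefix}_mean.csv",
               np.column_stack([model.wavelengths, model.mean_spectrum]),
               delimiter=",")
    meta = {
        "n_components": model.n_components,
        "variance_contribution": model.variance_contribution.tolist(),
        "scores": model.scores.tolist(),
    }
    with open(f"{prefix}_meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_pca(prefix: str | Path) -> PCAModel:
    loadings = np.atleast_2d(np.loadtxt(f"{prefix}_loadings.csv", delimiter=","))
    mean_table = np.loadtxt(f"{prefix}_mean.csv", delimiter=",")
    with open(f"{prefix}_meta.json") as fh:
        meta = json.load(fh)
    if loadings.shape[1] != meta["n_components"]:
        loadings = loadings.reshape(-1, meta["n_components"])
    return PCAModel(
        wavelengths=mean_table[:, 0],
        mean_spectrum=mean_table[:, 1],
        loadings=loadings,
        scores=np.asarray(meta["scores"]),
        variance_contribution=np.asarray(meta["variance_contribution"]),
    )
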