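"""Spectral data model, delimited-text I/O, train/test splitting, and the
synthetic milk-powder spectra generator.

The central container is :class:`SpectralDataset`: an ``n x p`` reflectance
matrix on a strictly increasing wavelength grid, one reference analyte value
per row (protein, g/100 g), a categorical brand label, and a unique sample id.

Because the measured milk-powder spectra behind the method are not public,
:func:`generate_synthetic` produces spectra with the same experimental design
(5 brands x 20 samples x 8 regions of interest = 800 rows, 125 bands spanning
400-1000 nm) and a physically plausible structure: a smooth reflectance base
curve minus Gaussian absorption bands whose depths are affine in the analyte
value, plus per-sample baseline drift and per-ROI noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectralDataset",
    "SyntheticSpec",
    "DEFAULT_BRAND_PROTEIN",
    "read_spectra",
    "write_spectra",
    "generate_synthetic",
    "generate_sparse_regression",
    "train_test_split",
]

#: Kjeldahl protein reference values (g/100 g) for the five milk-powder brands.
DEFAULT_BRAND_PROTEIN = (19.0, 23.8, 28.0, 25.4, 20.2)

ID_COL = "id"
BRAND_COL = "brand"
ANALYTE_COL = "protein_g_per_100g"


class ValidationError(ValueError):
    """Raised when a dataset violates its structural invariants."""


@dataclass
class SpectralDataset:
    """Reflectance spectra with per-sample reference analyte values.

    Parameters
    ----------
    wavelengths
        Strictly increasing wavelength grid in nm, length ``p``.
    reflectance
        ``n x p`` matrix of (corrected) reflectance values.
    analyte
        Length-``n`` vector of reference values, g/100 g; strictly positive.
    brand
        Length-``n`` vector of categorical labels.
    ids
        Length-``n`` vector of unique sample identifiers.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    analyte: np.ndarray
    brand: np.ndarray
    ids: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.atleast_2d(np.asarray(self.reflectance, dtype=float))
        self.analyte = np.asarray(self.analyte, dtype=float)
        self.brand = np.asarray(self.brand)
        self.ids = np.asarray(self.ids)
        n, p = self.reflectance.shape
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != p:
            raise ValidationError(
                f"wavelength grid length {len(self.wavelengths)} does not match "
                f"{p} reflectance columns"
            )
        if len(self.wavelengths) > 1 and np.any(np.diff(self.wavelengths) <= 0):
            bad = int(np.argmax(np.diff(self.wavelengths) <= 0))
            raise ValidationError(
                f"wavelengths must be strictly increasing (violated after index {bad})"
            )
        for name, vec in (("analyte", self.analyte), ("brand", self.brand), ("ids", self.ids)):
            if len(vec) != n:
                raise ValidationError(f"{name} has length {len(vec)}, expected n={n}")
        if not np.all(np.isfinite(self.reflectance)):
            r, c = np.argwhere(~np.isfinite(self.reflectance))[0]
            raise ValidationError(f"non-finite reflectance at row {r}, band column {c}")
        if not np.all(np.isfinite(self.analyte)):
            r = int(np.flatnonzero(~np.isfinite(self.analyte))[0])
            raise ValidationError(f"missing/non-finite analyte value at row {r}")
        if np.any(self.analyte <= 0):
            r = int(np.flatnonzero(self.analyte <= 0)[0])
            raise ValidationError(f"analyte must be > 0 (row {r})")
        if len(np.unique(self.ids)) != n:
            raise ValidationError("sample ids must be unique")

    @property
    def n(self) -> int:
        return self.reflectance.shape[0]

    @property
    def p(self) -> int:
        return self.reflectance.shape[1]

    def take(self, rows: np.ndarray) -> "SpectralDataset":
        """Row subset (positional indices), order preserved."""
        rows = np.asarray(rows)
        return SpectralDataset(
            wavelengths=self.wavelengths.copy(),
            reflectance=self.reflectance[rows],
            analyte=self.analyte[rows],
            brand=self.brand[rows],
            ids=self.ids[rows],
        )

    def select_bands(self, band_idx: np.ndarray) -> "SpectralDataset":
        """Column subset by band index (must remain increasing in wavelength)."""
        band_idx = np.sort(np.asarray(band_idx))
        return SpectralDataset(
            wavelengths=self.wavelengths[band_idx],
            reflectance=self.reflectance[:, band_idx],
            analyte=self.analyte.copy(),
            brand=self.brand.copy(),
            ids=self.ids.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {
            ID_COL: self.ids,
            BRAND_COL: self.brand,
            ANALYTE_COL: self.analyte,
        }
        df = pd.DataFrame(cols)
        wl_names = [str(float(w)) for w in self.wavelengths]
        spec = pd.DataFrame(self.reflectance, columns=wl_names, index=df.index)
        return pd.concat([df, spec], axis=1)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic milk-powder spectra generator.

    Defaults reproduce the study design: 5 brands x 20 samples x 8 ROIs,
    125 bands spanning 400-1000 nm, brand protein values from the reference
    table. Absorption-band depths are affine in the analyte so that linear
    calibration is recoverable by construction.
    """

    n_brands: int = 5
    samples_per_brand: int = 20
    rois_per_sample: int = 8
    brand_analyte: Sequence[float] = DEFAULT_BRAND_PROTEIN
    n_bands: int = 125
    wl_min: float = 400.0
    wl_max: float = 1000.0
    # Gaussian absorption components: broad pigment bands in the visible plus
    # overtone-like bands in 900-1000 nm. Only the NIR overtones couple to the
    # analyte (protein N-H/C-H overtones); visible pigment bands do not, so
    # wavelength selection has genuinely uninformative regions to discard.
    band_centers: Sequence[float] = (450.0, 670.0, 905.0, 935.0, 962.0, 988.0)
    band_widths: Sequence[float] = (40.0, 30.0, 12.0, 10.0, 14.0, 11.0)
    band_amplitudes: Sequence[float] = (0.08, 0.06, 0.10, 0.14, 0.18, 0.12)
    band_analyte_coupling: Sequence[float] = (0.0, 0.0, 1.0, 1.0, 1.0, 1.0)
    pigment_depth_sd: float = 0.1     # per-sample depth variation of uncoupled bands
    baseline_drift_sd: float = 0.01   # per-sample quadratic baseline coefficients
    roi_noise_sd: float = 0.005       # i.i.d. noise per ROI spectrum element
    sample_scale_sd: float = 0.01     # per-sample multiplicative amplitude jitter
    analyte_jitter_sd: float = 0.1    # per-sample analyte deviation from brand value (g/100 g)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_brands", "samples_per_brand", "rois_per_sample", "n_bands"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        for name in ("baseline_drift_sd", "roi_noise_sd", "sample_scale_sd",
                     "analyte_jitter_sd", "pigment_depth_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if len(self.brand_analyte) != self.n_brands:
            raise ValidationError(
                f"brand_analyte has {len(self.brand_analyte)} entries, expected {self.n_brands}"
            )
        if not (len(self.band_centers) == len(self.band_widths) == len(self.band_amplitudes)
                == len(self.band_analyte_coupling)):
            raise ValidationError(
                "band_centers/widths/amplitudes/analyte_coupling must have equal length")


def read_spectra(path, delimiter: str = ",") -> SpectralDataset:
    """Read a delimited spectra table into a :class:`SpectralDataset`.

    Expected layout: columns ``id``, ``brand``, ``protein_g_per_100g``, then
    one column per wavelength named by its nm value. Row order is preserved.
    """
    df = pd.read_csv(path, delimiter=delimiter, float_precision="round_trip")
    for col in (ID_COL, BRAND_COL, ANALYTE_COL):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column '{col}'")
    wl_cols = [c for c in df.columns if c not in (ID_COL, BRAND_COL, ANALYTE_COL)]
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric wavelength column header: {exc}") from exc
    if df[ANALYTE_COL].isna().any():
        row = int(df.index[df[ANALYTE_COL].isna()][0])
        raise ValidationError(f"{path}: blank analyte cell at row {row}")
    spec = df[wl_cols]
    if spec.isna().any().any():
        rc = np.argwhere(spec.isna().to_numpy())[0]
        raise ValidationError(
            f"{path}: missing reflectance at row {rc[0]}, column '{wl_cols[rc[1]]}'"
        )
    return SpectralDataset(
        wavelengths=wavelengths,
        reflectance=spec.to_numpy(dtype=float),
        analyte=df[ANALYTE_COL].to_numpy(dtype=float),
        brand=df[BRAND_COL].to_numpy(),
        ids=df[ID_COL].to_numpy(),
    )


def write_spectra(ds: SpectralDataset, path, delimiter: str = ",") -> None:
    """Write a dataset as delimited text readable by :func:`read_spectra`.

    Wavelength headers use the shortest round-trip float representation
    (always >= 6 significant digits of fidelity); values round-trip exactly.
    """
    try:
        # %.17g guarantees exact binary round-trip of float64 values
        ds.to_frame().to_csv(path, sep=delimiter, index=False, float_format="%.17g")
    except OSError as exc:
        raise OSError(f"failed writing spectra to {path}: {exc}") from exc


def _gaussian(x: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / width) ** 2)


def _base_curve(wl: np.ndarray) -> np.ndarray:
    # Smooth sigmoidal rise from ~0.58 at 400 nm to ~0.90 at 1000 nm,
    # qualitatively matching powdered-milk reflectance.
    return 0.55 + 0.35 / (1.0 + np.exp(-(wl - 550.0) / 70.0))


def generate_synthetic(spec: SyntheticSpec) -> SpectralDataset:
    """Generate a synthetic milk-powder-like reflectance dataset.

    Each spectrum is::

        scale_s * (base(wl) - sum_j depth_j(a_s) * G_j(wl)) + drift_s(wl) + eps

    with band depths ``depth_j(a) = amp_j * (k_j * a / 25 + (1 - k_j) * m_sj)``
    so that analyte-coupled bands (coupling ``k_j = 1``) deepen affinely with
    the per-sample analyte ``a_s`` (brand value + jitter) while uncoupled
    pigment bands fluctuate per sample (``m_sj ~ 1 + N(0, pigment_depth_sd)``)
    independently of the analyte — those spectral regions are genuinely
    uninformative for calibration, as pigment content is not protein-linked.
    ``drift_s`` is a per-sample quadratic baseline and ``eps`` i.i.d. per-ROI
    noise. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    wl = np.linspace(spec.wl_min, spec.wl_max, spec.n_bands)
    base = _base_curve(wl)
    profiles = np.stack(
        [a * _gaussian(wl, c, w)
         for c, w, a in zip(spec.band_centers, spec.band_widths, spec.band_amplitudes)]
    )  # (n_components, p)
    coupling = np.asarray(spec.band_analyte_coupling, dtype=float)
    u = np.linspace(-1.0, 1.0, spec.n_bands)

    rows, analyte, brand, ids = [], [], [], []
    for b in range(spec.n_brands):
        a_brand = float(spec.brand_analyte[b])
        for s in range(spec.samples_per_brand):
            a_s = a_brand + rng.normal(0.0, spec.analyte_jitter_sd) if spec.analyte_jitter_sd else a_brand
            a_s = max(a_s, 1e-3)
            if spec.pigment_depth_sd:
                m = 1.0 + rng.normal(0.0, spec.pigment_depth_sd, size=len(coupling))
            else:
                m = np.ones(len(coupling))
            per_band = coupling * (a_s / 25.0) + (1.0 - coupling) * m
            depth = per_band @ profiles
            scale = 1.0 + (rng.normal(0.0, spec.sample_scale_sd) if spec.sample_scale_sd else 0.0)
            if spec.baseline_drift_sd:
                c0, c1, c2 = rng.normal(0.0, spec.baseline_drift_sd, size=3)
            else:
                c0 = c1 = c2 = 0.0
            drift = c0 + c1 * u + c2 * u**2
            clean = scale * (base - depth) + drift
            for r in range(spec.rois_per_sample):
                noise = rng.normal(0.0, spec.roi_noise_sd, size=spec.n_bands) if spec.roi_noise_sd else 0.0
                rows.append(clean + noise)
                analyte.append(a_s)
                brand.append(f"brand{b + 1}")
                ids.append(f"B{b + 1}_S{s:02d}_R{r}")
    return SpectralDataset(
        wavelengths=wl,
        reflectance=np.asarray(rows),
        analyte=np.asarray(analyte),
        brand=np.asarray(brand),
        ids=np.asarray(ids),
    )


def generate_sparse_regression(
    n: int,
    p: int,
    informative: Sequence[int],
    snr: float = 20.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Regression design where y depends on a known sparse subset of bands.

    ``X`` is i.i.d. standard normal; ``y`` is a unit-weight sum over the
    informative columns plus Gaussian noise with ``var(signal)/var(noise) = snr``.
    Used as ground truth for wavelength-selection recovery checks.
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    informative = np.asarray(informative, dtype=int)
    signal = X[:, informative].sum(axis=1)
    noise_sd = float(np.sqrt(signal.var() / snr)) if snr > 0 else 0.0
    y = signal + rng.normal(0.0, noise_sd, size=n)
    return X, y


def train_test_split(
    ds: SpectralDataset,
    ratio: float = 0.7,
    seed: int = 0,
    stratify: bool = True,
) -> tuple[SpectralDataset, SpectralDataset]:
    """Disjoint, exhaustive train/test partition, deterministic given seed.

    With ``stratify`` on, the split is performed within each brand so brand
    proportions are preserved to within one sample.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    rng = np.random.default_rng(seed)
    n = ds.n
    if stratify:
        train_rows = []
        test_rows = []
        for b in np.unique(ds.brand):
            rows = np.flatnonzero(ds.brand == b)
            if len(rows) < 2:
                raise ValueError(
                    f"brand '{b}' has {len(rows)} row(s); stratified split needs >= 2"
                )
            perm = rng.permutation(rows)
            k = int(np.floor(len(rows) * ratio + 0.5))
            k = min(max(k, 1), len(rows) - 1)
            train_rows.append(perm[:k])
            test_rows.append(perm[k:])
        train_rows = np.concatenate(train_rows)
        test_rows = np.concatenate(test_rows)
    else:
        perm = rng.permutation(n)
        k = int(np.floor(n * ratio + 0.5))
        k = min(max(k, 1), n - 1)
        train_rows, test_rows = perm[:k], perm[k:]
    return ds.take(np.sort(train_rows)), ds.take(np.sort(test_rows))
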