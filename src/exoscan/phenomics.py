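"""Leaf hyperspectral indices and broad-sense heritability.

The index registry reproduces the study's printed formula set exactly,
including two entries (SIPI and NDMI) whose printed forms differ from the
variants more common in the wider literature; a literature-style SIPI is
available behind an explicit flag, but the printed form is the default.

Broad-sense heritability across environments (years) is

    H2 = sigma_g2 / (sigma_g2 + sigma_ge2 / e + sigma_e2 / (r * e))

with r replicates and e environments.  Variance components come from the
expected mean squares of a balanced two-way genotype x environment ANOVA
with replication:

    sigma_e2  = MS_error
    sigma_ge2 = (MS_GxE - MS_error) / r
    sigma_g2  = (MS_G - MS_GxE) / (r * e)

negative component estimates are truncated at 0 before the ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

_EPS = 1e-9

REQUIRED_WAVELENGTHS = (
    415, 435, 475, 500, 531, 550, 570, 650, 670, 675, 680, 700, 750,
    760, 780, 800, 850, 900, 1100, 1200, 1300, 1450, 1649, 1650, 1722,
)


@dataclass
class ReflectanceSpectrum:
    """One sample's reflectance over an ascending wavelength grid (nm)."""

    sample: str
    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths.shape != self.reflectance.shape:
            raise ValueError("wavelength and reflectance grids must match")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly ascending")

    def R(self, nm: float) -> float:
        """Reflectance at a wavelength: nearest neighbour within 1 nm,
        otherwise linear interpolation (for grids coarser than 1 nm)."""
        wl = self.wavelengths
        if nm < wl[0] or nm > wl[-1]:
            raise ValueError(f"wavelength {nm} nm outside spectrum range")
        i = int(np.argmin(np.abs(wl - nm)))
        if abs(wl[i] - nm) <= 1.0:
            return float(self.reflectance[i])
        return float(np.interp(nm, wl, self.reflectance))


def _nd(a: float, b: float) -> float:
    return _ratio(a - b, a + b)


def _ratio(num: float, den: float) -> float:
    if abs(den) < _EPS:
        warnings.warn("near-zero denominator in spectral index; returning NaN",
                      stacklevel=3)
        return float("nan")
    return num / den


# The registry: name -> formula over R(lambda).  Order is the reporting order.
INDEX_REGISTRY: dict[str, Callable] = {
    "GNDVI": lambda R: _nd(R(780), R(550)),
    "RNDVI": lambda R: _nd(R(780), R(670)),
    "NDII": lambda R: _nd(R(850), R(1650)),
    "NDMI": lambda R: _nd(R(1649), R(1722)),
    "EVI": lambda R: 2.5 * _ratio(R(900) - R(680),
                                  R(900) + 6 * R(680) - 7.5 * R(475) + 1),
    "RARSa": lambda R: _ratio(R(675), R(700)),
    "PSSRa": lambda R: _ratio(R(800), R(675)),
    "RARSb": lambda R: _ratio(R(675), R(650) * R(700)),
    "RARSc": lambda R: _ratio(R(760), R(500)),
    "SIPI": lambda R: _ratio(R(800) - R(435), R(415) + R(435)),
    "TotalChl_550": lambda R: _ratio(R(750), R(550)),
    "TotalChl_700": lambda R: _ratio(R(750), R(700)),
    "NPQI": lambda R: _nd(R(415), R(435)),
    "PSRI": lambda R: _ratio(R(680) - R(570), R(531) - R(570)),
    "WI2": lambda R: _ratio(R(1100), R(1200)),
    "WI3": lambda R: _ratio(R(1300), R(1450)),
    "WI4": lambda R: _ratio(R(1300), R(1200)),
}

# literature-style alternative kept behind an explicit opt-in
SIPI_LITERATURE = lambda R: _ratio(R(800) - R(445), R(800) - R(680))


def compute_index(
    spectrum: ReflectanceSpectrum, name: str, sipi_variant: str = "printed"
) -> float:
    """Evaluate one registry index on a spectrum.

    ``sipi_variant='literature'`` swaps SIPI for (R800-R445)/(R800-R680).
    Near-zero denominators (possible for PSRI when R531 ~ R570) give NaN with
    a warning rather than an exception.
    """
    if name not in INDEX_REGISTRY:
        raise KeyError(f"unknown index {name!r}; known: {list(INDEX_REGISTRY)}")
    if name == "SIPI" and sipi_variant == "literature":
        return float(SIPI_LITERATURE(spectrum.R))
    return float(INDEX_REGISTRY[name](spectrum.R))


def spectra_from_wide(table: pd.DataFrame) -> list[ReflectanceSpectrum]:
    """Wide spectra table (wavelength_nm + one column per sample) to spectra."""
    if "wavelength_nm" not in table.columns:
        raise ValueError("wide spectra table needs a 'wavelength_nm' column")
    wl = table["wavelength_nm"].to_numpy(dtype=float)
    return [
        ReflectanceSpectrum(sample=c, wavelengths=wl,
                            reflectance=table[c].to_numpy(dtype=float))
        for c in table.columns
        if c != "wavelength_nm"
    ]


def compute_all_indices(
    spectra: pd.DataFrame | Sequence[ReflectanceSpectrum],
    names: Sequence[str] | None = None,
    sipi_variant: str = "printed",
) -> pd.DataFrame:
    """Sample x index matrix; per-cell NaN propagates (never dropped)."""
    if isinstance(spectra, pd.DataFrame):
        spectra = spectra_from_wide(spectra)
    names = list(INDEX_REGISTRY) if names is None else list(names)
    unknown = set(names) - set(INDEX_REGISTRY)
    if unknown:
        raise KeyError(f"unknown indices: {sorted(unknown)}")
    rows = {
        sp.sample: [compute_index(sp, n, sipi_variant=sipi_variant) for n in names]
        for sp in spectra
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=names)


# ---------------------------------------------------------------------------
# broad-sense heritability
# ---------------------------------------------------------------------------

@dataclass
class HeritabilityResult:
    trait: str
    sigma_g2: float
    sigma_ge2: float
    sigma_e2: float
    r: int
    e: int
    H2: float
    h2_class: str

    def as_row(self) -> dict:
        return {
            "trait": self.trait, "sigma_g2": self.sigma_g2,
            "sigma_ge2": self.sigma_ge2, "sigma_e2": self.sigma_e2,
            "H2": self.H2, "class": self.h2_class,
        }


def h2_from_components(
    sigma_g2: float, sigma_ge2: float, sigma_e2: float, e: int, r: int
) -> float:
    """The heritability ratio itself (components floored at 0 first)."""
    g = max(sigma_g2, 0.0)
    ge = max(sigma_ge2, 0.0)
    err = max(sigma_e2, 0.0)
    denom = g + ge / e + err / (r * e)
    return 0.0 if denom == 0 else g / denom


def classify_h2(h2: float) -> str:
    """low: H2 < 0.30; medium: 0.30 <= H2 < 0.60; high: H2 >= 0.60."""
    if not (0.0 <= h2 <= 1.0):
        raise ValueError("H2 must be in [0, 1]")
    if h2 < 0.30:
        return "low"
    if h2 < 0.60:
        return "medium"
    return "high"


def anova_mean_squares(values: np.ndarray) -> tuple[float, float, float]:
    """MS_G, MS_GE, MS_error of a balanced genotype x environment x rep array."""
    g, e, r = values.shape
    grand = values.mean()
    m_g = values.mean(axis=(1, 2))
    m_e = values.mean(axis=(0, 2))
    m_ge = values.mean(axis=2)
    ss_g = r * e * np.sum((m_g - grand) ** 2)
    ss_ge = r * np.sum((m_ge - m_g[:, None] - m_e[None, :] + grand) ** 2)
    ss_err = np.sum((values - m_ge[:, :, None]) ** 2)
    ms_g = ss_g / (g - 1)
    ms_ge = ss_ge / ((g - 1) * (e - 1))
    ms_err = ss_err / (g * e * (r - 1))
    return float(ms_g), float(ms_ge), float(ms_err)


def heritability(
    table: pd.DataFrame,
    trait: str,
    r: int | None = None,
    e: int | None = None,
) -> HeritabilityResult:
    """Estimate variance components and H2 for one trait.

    ``table`` is long format with columns genotype, year, rep, trait, value.
    The design must be balanced (every genotype x year cell with the same
    replicate count); ``r`` and ``e`` default to the observed design but can
    be overridden when the effective replication differs from the table
    layout (e.g. subsampled measurements).
    """
    sub = table[table["trait"] == trait] if "trait" in table.columns else table
    if sub.empty:
        raise ValueError(f"no records for trait {trait!r}")
    genotypes = sorted(sub["genotype"].unique())
    years = sorted(sub["year"].unique())
    if len(genotypes) < 2 or len(years) < 2:
        raise ValueError("need >= 2 genotypes and >= 2 environments")
    cell_counts = sub.groupby(["genotype", "year"])["value"].count()
    if len(cell_counts) != len(genotypes) * len(years) or cell_counts.nunique() != 1:
        raise ValueError(
            "unbalanced design: every genotype x year cell needs the same "
            "replicate count (a REML fit outside this closed-form estimator "
            "would be required)"
        )
    r_obs = int(cell_counts.iloc[0])
    if r_obs < 2:
        raise ValueError("need >= 2 replicates per genotype x year cell")
    e_obs = len(years)
    values = (
        sub.sort_values(["genotype", "year", "rep"])["value"]
        .to_numpy(dtype=float)
        .reshape(len(genotypes), e_obs, r_obs)
    )
    ms_g, ms_ge, ms_err = anova_mean_squares(values)
    r_eff = r_obs if r is None else int(r)
    e_eff = e_obs if e is None else int(e)
    sigma_e2 = ms_err
    sigma_ge2 = (ms_ge - ms_err) / r_obs
    sigma_g2 = (ms_g - ms_ge) / (r_obs * e_obs)
    h2 = h2_from_components(sigma_g2, sigma_ge2, sigma_e2, e_eff, r_eff)
    return HeritabilityResult(
        trait=trait,
        sigma_g2=max(sigma_g2, 0.0),
        sigma_ge2=max(sigma_ge2, 0.0),
        sigma_e2=max(sigma_e2, 0.0),
        r=r_eff,
        e=e_eff,
        H2=h2,
        h2_class=classify_h2(h2),
    )


def heritability_report(
    table: pd.DataFrame, r: int | None = None, e: int | None = None
) -> pd.DataFrame:
    """One heritability row per trait in the table."""
    traits = sorted(table["trait"].unique())
    return pd.DataFrame([heritability(table, t, r=r, e=e).as_row() for t in traits])
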