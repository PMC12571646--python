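"""Far-UV circular dichroism analysis of PPII helix content.

PPII helices show a weak positive CD band near 212-217 nm whose intensity
scales with the helical population.  The empirical calibration of Stellwagen
and co-workers maps the maximum mean residue ellipticity between 210 and
230 nm onto a population:

    %PPII = 100 * (theta_max + 5560) / 15140      [deg cm^2 dmol^-1]

where -5560 and +9580 (= 15140 - 5560) are the 0% and 100% endpoints.
Thermal melts followed at a fixed wavelength (217 nm by convention) are fit
with ordinary least squares; a linear, non-cooperative signal loss on
heating is the PPII-to-coil signature, in contrast to the sigmoidal melts of
cooperatively folded domains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CDSpectrum",
    "MeltTrace",
    "MeltFit",
    "LinearityReport",
    "CDMelt",
    "theta_max",
    "ppii_population",
    "fit_melt",
    "difference_spectrum",
    "linearity_check",
    "mre_from_millidegrees",
    "PPII_ZERO_MRE",
    "PPII_RANGE_MRE",
]

#: Mean residue ellipticity of the 0% PPII endpoint (deg cm^2 dmol^-1).
PPII_ZERO_MRE = -5560.0
#: Dynamic range of the calibration; the 100% endpoint sits at +9580.
PPII_RANGE_MRE = 15140.0


@dataclass
class CDSpectrum:
    """A far-UV CD spectrum: mean residue ellipticity vs wavelength.

    ``mre`` is in deg cm^2 dmol^-1 on a strictly increasing wavelength grid
    in nm; ``temperature`` in deg C.
    """

    wavelengths: np.ndarray
    mre: np.ndarray
    temperature: float = 25.0
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.mre = np.asarray(self.mre, dtype=float)
        if self.wavelengths.shape != self.mre.shape or self.wavelengths.ndim != 1:
            raise ValueError("wavelengths and mre must be equal-length 1-D arrays")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.wavelengths.size and (
            self.wavelengths[0] < 180.0 or self.wavelengths[-1] > 300.0
        ):
            raise ValueError("wavelengths must lie within 180-300 nm")


@dataclass
class MeltTrace:
    """Ellipticity at one wavelength followed across temperature."""

    temperatures: np.ndarray
    mre: np.ndarray
    wavelength: float = 217.0

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.mre = np.asarray(self.mre, dtype=float)
        if self.temperatures.shape != self.mre.shape or self.temperatures.ndim != 1:
            raise ValueError("temperatures and mre must be equal-length 1-D arrays")
        if self.temperatures.size < 3:
            raise ValueError("a melt trace needs at least 3 points for fitting")


@dataclass(frozen=True)
class MeltFit:
    """OLS fit of a melt trace: mre = intercept + slope * T.

    ``r`` is the Pearson correlation of the (T, mre) pairs; ``degenerate``
    marks a zero-variance (flat) response, for which slope = 0 and r is
    reported as 0 rather than undefined.
    """

    intercept: float
    slope: float
    r: float
    intercept_stderr: float = float("nan")
    slope_stderr: float = float("nan")
    degenerate: bool = False

    def predict(self, temperatures) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(temperatures, dtype=float)


def theta_max(
    spec: CDSpectrum, lo: float = 210.0, hi: float = 230.0
) -> tuple[float, float]:
    """Maximum sampled MRE in [lo, hi] nm; returns (wavelength, mre).

    No interpolation: the maximum is read directly off the sampled grid, as
    it is from a measured spectrum.  Ties break toward the lower wavelength.
    """
    if spec.wavelengths.size == 0:
        raise ValueError("empty spectrum")
    if spec.wavelengths[0] > lo or spec.wavelengths[-1] < hi:
        raise ValueError(
            f"spectrum covers {spec.wavelengths[0]:g}-{spec.wavelengths[-1]:g} nm, "
            f"not the requested {lo:g}-{hi:g} nm"
        )
    mask = (spec.wavelengths >= lo) & (spec.wavelengths <= hi)
    if not mask.any():
        raise ValueError(f"no sampled wavelengths in [{lo:g}, {hi:g}] nm")
    wl = spec.wavelengths[mask]
    th = spec.mre[mask]
    i = int(np.argmax(th))  # argmax returns the first (lowest-wavelength) tie
    return float(wl[i]), float(th[i])


def ppii_population(theta_max_value: float) -> float:
    """PPII population in percent from the empirical CD calibration.

    %PPII = 100 * (theta + 5560) / 15140.  The value is returned unclamped;
    results outside [0, 100] trigger a warning, since they indicate a unit
    or baseline problem rather than a physical population.
    """
    theta = float(theta_max_value)
    if not np.isfinite(theta):
        raise ValueError("theta_max must be finite")
    pop = 100.0 * (theta - PPII_ZERO_MRE) / PPII_RANGE_MRE
    if pop < 0.0 or pop > 100.0:
        warnings.warn(
            f"PPII population {pop:.1f}% outside [0, 100]; "
            "check units/baseline of the ellipticity",
            stacklevel=2,
        )
    return pop


def fit_melt(trace: MeltTrace) -> MeltFit:
    """Ordinary least squares of MRE on temperature.

    A negative slope is the PPII-loss signature.  All-identical temperatures
    are an error; a flat (zero-variance) response returns slope 0 with r
    reported as 0 and the ``degenerate`` flag set, so batch processing
    survives flat controls.
    """
    T, y = trace.temperatures, trace.mre
    if np.unique(T).size < 2:
        raise ValueError("melt fit needs at least 2 distinct temperatures")
    if np.allclose(y, y[0]):
        return MeltFit(
            intercept=float(y[0]), slope=0.0, r=0.0,
            intercept_stderr=0.0, slope_stderr=0.0, degenerate=True,
        )
    res = stats.linregress(T, y)
    return MeltFit(
        intercept=float(res.intercept),
        slope=float(res.slope),
        r=float(res.rvalue),
        intercept_stderr=float(res.intercept_stderr),
        slope_stderr=float(res.stderr),
    )


def difference_spectrum(
    a: CDSpectrum, b: CDSpectrum, on_mismatch: str = "error"
) -> CDSpectrum:
    """Pointwise difference a - b of two spectra.

    Grids must be identical; with ``on_mismatch="intersect"`` the spectra
    are first restricted to their common wavelengths.  Disjoint grids are
    always an error.  The label records the temperature pair.
    """
    if np.array_equal(a.wavelengths, b.wavelengths):
        wl, ya, yb = a.wavelengths, a.mre, b.mre
    elif on_mismatch == "intersect":
        wl, ia, ib = np.intersect1d(a.wavelengths, b.wavelengths, return_indices=True)
        if wl.size == 0:
            raise ValueError("spectra share no common wavelengths")
        ya, yb = a.mre[ia], b.mre[ib]
    else:
        raise ValueError(
            "wavelength grids differ; pass on_mismatch='intersect' to use "
            "the common grid"
        )
    return CDSpectrum(
        wavelengths=wl.copy(),
        mre=ya - yb,
        temperature=a.temperature,
        label=f"{a.temperature:g}C - {b.temperature:g}C",
    )


def _longest_sign_run(signs: np.ndarray) -> int:
    longest = run = 0
    prev = 0
    for s in signs:
        if s == 0:
            run, prev = 0, 0
            continue
        run = run + 1 if s == prev else 1
        prev = s
        longest = max(longest, run)
    return longest


def _runs_test_pvalue(signs: np.ndarray) -> float:
    """One-sided Wald-Wolfowitz runs test: small p means too few sign runs
    (systematic curvature)."""
    s = signs[signs != 0]
    n_pos = int(np.sum(s > 0))
    n_neg = int(np.sum(s < 0))
    n = n_pos + n_neg
    if n_pos == 0 or n_neg == 0 or n < 3:
        return 1.0
    runs = 1 + int(np.sum(s[1:] != s[:-1]))
    mu = 2.0 * n_pos * n_neg / n + 1.0
    var = 2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n) / (n**2 * (n - 1.0))
    if var <= 0:
        return 1.0
    z = (runs - mu) / np.sqrt(var)
    return float(stats.norm.cdf(z))


@dataclass(frozen=True)
class LinearityReport:
    """Diagnostics for the non-cooperative (linear) melt criterion."""

    is_linear: bool
    fit: MeltFit
    residuals: np.ndarray
    longest_sign_run: int
    runs_pvalue: float


def linearity_check(
    trace: MeltTrace,
    r_threshold: float = 0.95,
    runs_alpha: float = 0.01,
    max_sign_run: int | None = None,
) -> LinearityReport:
    """Is the melt consistent with a linear, non-cooperative transition?

    Passes when |r| of the OLS fit is at least ``r_threshold`` (the printed
    melt fits of PPII peptides reach R = 0.96-0.98) and the residual signs
    show no systematic curvature: a one-sided runs test must not reject at
    ``runs_alpha``, and, if ``max_sign_run`` is given, the longest run of
    same-sign residuals must not exceed it.  Residuals below 1e-9 of the
    signal scale count as zero so that exact fits pass trivially.
    """
    fit = fit_melt(trace)
    residuals = trace.mre - fit.predict(trace.temperatures)
    scale = max(np.max(np.abs(trace.mre)), 1.0)
    signs = np.sign(np.where(np.abs(residuals) < 1e-9 * scale, 0.0, residuals)).astype(int)
    longest = _longest_sign_run(signs)
    p_runs = _runs_test_pvalue(signs)
    ok = (
        abs(fit.r) >= r_threshold
        and not fit.degenerate
        and p_runs >= runs_alpha
        and (max_sign_run is None or longest <= max_sign_run)
    )
    if fit.degenerate:
        ok = False
    return LinearityReport(
        is_linear=bool(ok),
        fit=fit,
        residuals=residuals,
        longest_sign_run=longest,
        runs_pvalue=p_runs,
    )


def mre_from_millidegrees(
    theta_mdeg: float | np.ndarray,
    peptide_mass_da: float,
    n_residues: int,
    pathlength_cm: float,
    conc_mg_per_ml: float,
) -> float | np.ndarray:
    """Convert raw ellipticity (millidegrees) to mean residue ellipticity.

    Uses MRE = theta_mdeg * MRW / (10 * pathlength * concentration) with the
    mean residue weight MRW = mass / (n_residues - 1), i.e. per peptide
    bond.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues for a peptide bond")
    if pathlength_cm <= 0 or conc_mg_per_ml <= 0:
        raise ValueError("pathlength and concentration must be positive")
    mrw = peptide_mass_da / (n_residues - 1)
    return np.asarray(theta_mdeg, dtype=float) * mrw / (
        10.0 * pathlength_cm * conc_mg_per_ml
    )


class CDMelt:
    """Thermal-melt model: MRE at a fixed wavelength, linear in temperature."""

    def __init__(self, trace: MeltTrace):
        self.trace = trace

    def fit(self) -> "CDMeltResults":
        return CDMeltResults(model=self, fit_=fit_melt(self.trace))


@dataclass
class CDMeltResults:
    """Fitted melt line with linearity diagnostics and population mapping."""

    model: CDMelt
    fit_: MeltFit

    @property
    def params(self) -> dict[str, float]:
        return {"intercept": self.fit_.intercept, "slope": self.fit_.slope}

    @property
    def bse(self) -> dict[str, float]:
        return {
            "intercept": self.fit_.intercept_stderr,
            "slope": self.fit_.slope_stderr,
        }

    @property
    def rvalue(self) -> float:
        return self.fit_.r

    def predict(self, temperatures) -> np.ndarray:
        return self.fit_.predict(temperatures)

    def linearity(self, **kwargs) -> LinearityReport:
        return linearity_check(self.model.trace, **kwargs)

    def population_at(self, temperature: float) -> float:
        """PPII population from the fitted line, via the CD calibration.

        Meaningful when the trace was recorded at the spectral maximum;
        at 217 nm it underestimates the 212 nm maximum slightly.
        """
        return ppii_population(float(self.predict(temperature)))

    def summary(self) -> str:
        t = self.model.trace
        lin = self.linearity()
        lines = [
            "CD thermal melt fit (OLS)",
            f"  wavelength: {t.wavelength:g} nm   points: {t.temperatures.size}"
            f"   T range: {t.temperatures.min():g}-{t.temperatures.max():g} C",
            f"  [theta] = {self.fit_.intercept:.6g} {self.fit_.slope:+.6g} * T(C)"
            f"   R = {self.fit_.r:.4f}",
            f"  stderr: intercept {self.fit_.intercept_stderr:.3g},"
            f" slope {self.fit_.slope_stderr:.3g}",
            f"  linear (non-cooperative): {lin.is_linear}"
            f"  (runs-test p = {lin.runs_pvalue:.3g},"
            f" longest sign run = {lin.longest_sign_run})",
        ]
        if self.fit_.degenerate:
            lines.append("  note: flat response; fit degenerate")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.model.trace
        ax.plot(t.temperatures, t.mre, "ko", label="data")
        ax.plot(t.temperatures, self.predict(t.temperatures), "b-", label="OLS fit")
        ax.set_xlabel("temperature (C)")
        ax.set_ylabel(f"[theta] at {t.wavelength:g} nm (deg cm$^2$ dmol$^{{-1}}$)")
        ax.legend()
        return ax
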